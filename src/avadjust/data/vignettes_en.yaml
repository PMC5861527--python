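# English anchoring-vignette texts for the Big Five, three per factor,
# ordered by design rank (1 = low intended trait level, 3 = high).  Each is
# rated on the same 5-point agreement scale as the self-report items.  Note
# the neuroticism set is worded in the emotional-stability direction.
response_scale:
  - Disagree strongly
  - Disagree a little
  - Neither agree nor disagree
  - Agree a little
  - Agree strongly
conscientiousness:
  - id: conscientiousness_v1
    rank: 1
    text: >-
      Sophia tends to be somewhat careless. Other workers also comment that
      she is lazy. Sophia often also appears disorganized. Based on this
      information, to what extent do you agree with the statement "Sophia is
      conscientious/hard-working"?
  - id: conscientiousness_v2
    rank: 2
    text: >-
      Jacob is a reliable worker and does all work with great efficiency,
      but he is easily distracted. Based on this information, to what extent
      do you agree with the statement "Jacob is conscientious/hard-working"?
  - id: conscientiousness_v3
    rank: 3
    text: >-
      Emma always does a thorough job. She perseveres until all tasks are
      finished. Emma also makes plans and follows through with them. Based
      on this information, to what extent do you agree with the statement
      "Emma is conscientious/hard-working"?
agreeableness:
  - id: agreeableness_v1
    rank: 1
    text: >-
      Jean tends to disagree with others, and as a result often starts
      quarrels. Indeed, many people consider Jean quite rude. Based on this
      information, to what extent do you agree with the statement "Jean is
      an agreeable person"?
  - id: agreeableness_v2
    rank: 2
    text: >-
      Even though Nicole is helpful and unselfish with others, some people
      find her cold and unfriendly. This does not matter so much, as she has
      a forgiving nature. Based on this information, to what extent do you
      agree with the statement "Nicole is an agreeable person"?
  - id: agreeableness_v3
    rank: 3
    text: >-
      Claude is considerate and kind to almost everyone. He is very
      trusting, and finds it easy to cooperate with others. Based on this
      information, to what extent do you agree with the statement "Claude is
      an agreeable person"?
neuroticism:
  - id: neuroticism_v1
    rank: 1
    text: >-
      Carine frequently appears quite depressed to other people. She gets
      nervous easily. Based on this information, to what extent do you agree
      with the statement "Carine is emotionally stable"?
  - id: neuroticism_v2
    rank: 2
    text: >-
      Although in tense situations Paul remains calm, he can be quite moody.
      And he tends to worry quite a lot. Based on this information, to what
      extent do you agree with the statement "Paul is emotionally stable"?
  - id: neuroticism_v3
    rank: 3
    text: >-
      Aline always appears relaxed and to handle stress well. Indeed, she
      never comes across as upset. Aline remains calm in all situations.
      Based on this information, to what extent do you agree with the
      statement "Aline is emotionally stable"?
openness:
  - id: openness_v1
    rank: 1
    text: >-
      Emmanuel has few artistic interests, and is not especially
      sophisticated either in music or literature. This has led some people
      to observe that Emmanuel does not appear especially curious about
      anything. Based on this information, to what extent do you agree with
      the statement "Emmanuel is open-minded"?
  - id: openness_v2
    rank: 2
    text: >-
      Emma has an active imagination. This has led some people to calling
      her a deep thinker. Even so Emma prefers work that is routine. Based
      on this information, to what extent do you agree with the statement
      "Emma is open-minded"?
  - id: openness_v3
    rank: 3
    text: >-
      Jean Bosco is original and always coming up with new ideas. This has
      led some people to calling him inventive. But beyond this, Jean Bosco
      values artistic, aesthetic experiences. Based on this information, to
      what extent do you agree with the statement "Jean Bosco is
      open-minded"?
extraversion:
  - id: extraversion_v1
    rank: 1
    text: >-
      Claudine is very reserved. She tends to be quiet no matter what the
      circumstance. Indeed, people find her shy and inhibited. Based on this
      information, to what extent do you agree with the statement "Claudine
      is extraverted"?
  - id: extraversion_v2
    rank: 2
    text: >-
      Emile is often talkative and generates a lot of enthusiasm in others.
      But on his day, Emile can be rather shy and inhibited. Based on this
      information, to what extent do you agree with the statement "Emile is
      extraverted"?
  - id: extraversion_v3
    rank: 3
    text: >-
      Rosette has an assertive personality, and as a result appears outgoing
      and sociable. Indeed, people are always commenting on how full of
      energy Rosette is. Based on this information, to what extent do you
      agree with the statement "Rosette is extraverted"?
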