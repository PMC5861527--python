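# Packaged codebook for the 44-item Big Five Inventory administered with
# three anchoring vignettes per factor, a 5-item life-satisfaction scale and
# a 7-item counterproductive-behavior scale (7-point).
#
# Orientation convention: every item is keyed toward its construct's
# *vignette* direction.  The neuroticism vignettes describe emotional
# stability, so neuroticism-worded items carry reverse: true here and the
# construct is listed under score_reversed (scale scores are flipped back to
# the neuroticism direction at scoring time).  The keying follows the
# published BFI-44 scoring and is user-overridable: edit this file or build
# a SurveyCodebook directly.
constructs: [extraversion, agreeableness, conscientiousness, neuroticism, openness]
items:
  # Extraversion: 1, 6R, 11, 16, 21R, 26, 31R, 36
  - {id: bfi1, construct: extraversion, reverse: false, scale: 5}
  - {id: bfi6, construct: extraversion, reverse: true, scale: 5}
  - {id: bfi11, construct: extraversion, reverse: false, scale: 5}
  - {id: bfi16, construct: extraversion, reverse: false, scale: 5}
  - {id: bfi21, construct: extraversion, reverse: true, scale: 5}
  - {id: bfi26, construct: extraversion, reverse: false, scale: 5}
  - {id: bfi31, construct: extraversion, reverse: true, scale: 5}
  - {id: bfi36, construct: extraversion, reverse: false, scale: 5}
  # Agreeableness: 2R, 7, 12R, 17, 22, 27R, 32, 37R, 42
  - {id: bfi2, construct: agreeableness, reverse: true, scale: 5}
  - {id: bfi7, construct: agreeableness, reverse: false, scale: 5}
  - {id: bfi12, construct: agreeableness, reverse: true, scale: 5}
  - {id: bfi17, construct: agreeableness, reverse: false, scale: 5}
  - {id: bfi22, construct: agreeableness, reverse: false, scale: 5}
  - {id: bfi27, construct: agreeableness, reverse: true, scale: 5}
  - {id: bfi32, construct: agreeableness, reverse: false, scale: 5}
  - {id: bfi37, construct: agreeableness, reverse: true, scale: 5}
  - {id: bfi42, construct: agreeableness, reverse: false, scale: 5}
  # Conscientiousness: 3, 8R, 13, 18R, 23R, 28, 33, 38, 43R
  - {id: bfi3, construct: conscientiousness, reverse: false, scale: 5}
  - {id: bfi8, construct: conscientiousness, reverse: true, scale: 5}
  - {id: bfi13, construct: conscientiousness, reverse: false, scale: 5}
  - {id: bfi18, construct: conscientiousness, reverse: true, scale: 5}
  - {id: bfi23, construct: conscientiousness, reverse: true, scale: 5}
  - {id: bfi28, construct: conscientiousness, reverse: false, scale: 5}
  - {id: bfi33, construct: conscientiousness, reverse: false, scale: 5}
  - {id: bfi38, construct: conscientiousness, reverse: false, scale: 5}
  - {id: bfi43, construct: conscientiousness, reverse: true, scale: 5}
  # Neuroticism, oriented toward stability (vignette direction):
  # neuroticism-worded items 4, 14, 19, 29, 39 are reversed here; the
  # BFI-reversed (stability-worded) items 9, 24, 34 are not.
  - {id: bfi4, construct: neuroticism, reverse: true, scale: 5}
  - {id: bfi9, construct: neuroticism, reverse: false, scale: 5}
  - {id: bfi14, construct: neuroticism, reverse: true, scale: 5}
  - {id: bfi19, construct: neuroticism, reverse: true, scale: 5}
  - {id: bfi24, construct: neuroticism, reverse: false, scale: 5}
  - {id: bfi29, construct: neuroticism, reverse: true, scale: 5}
  - {id: bfi34, construct: neuroticism, reverse: false, scale: 5}
  - {id: bfi39, construct: neuroticism, reverse: true, scale: 5}
  # Openness: 5, 10, 15, 20, 25, 30, 35R, 40, 41R, 44
  - {id: bfi5, construct: openness, reverse: false, scale: 5}
  - {id: bfi10, construct: openness, reverse: false, scale: 5}
  - {id: bfi15, construct: openness, reverse: false, scale: 5}
  - {id: bfi20, construct: openness, reverse: false, scale: 5}
  - {id: bfi25, construct: openness, reverse: false, scale: 5}
  - {id: bfi30, construct: openness, reverse: false, scale: 5}
  - {id: bfi35, construct: openness, reverse: true, scale: 5}
  - {id: bfi40, construct: openness, reverse: false, scale: 5}
  - {id: bfi41, construct: openness, reverse: true, scale: 5}
  - {id: bfi44, construct: openness, reverse: false, scale: 5}
vignettes:
  extraversion: {ids: [extraversion_v1, extraversion_v2, extraversion_v3], scale: 5}
  agreeableness: {ids: [agreeableness_v1, agreeableness_v2, agreeableness_v3], scale: 5}
  conscientiousness: {ids: [conscientiousness_v1, conscientiousness_v2, conscientiousness_v3], scale: 5}
  neuroticism: {ids: [neuroticism_v1, neuroticism_v2, neuroticism_v3], scale: 5}
  openness: {ids: [openness_v1, openness_v2, openness_v3], scale: 5}
outcomes:
  - {id: life_satisfaction, ids: [ls_1, ls_2, ls_3, ls_4, ls_5], scale: 5, reverse: []}
  - {id: counterproductive, ids: [cb_1, cb_2, cb_3, cb_4, cb_5, cb_6, cb_7], scale: 7, reverse: []}
group_column: group
score_reversed: [neuroticism]
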