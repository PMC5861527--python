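"""Accessors for packaged survey materials: the 44-item Big Five codebook
(with vignette sets and outcome scales) and the English vignette texts."""

from __future__ import annotations

from importlib import resources as _ir

import yaml

from .datamodel import SurveyCodebook

__all__ = ["bfi44_codebook", "vignette_texts"]


def _load(name: str) -> dict:
    with _ir.files("avadjust.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def bfi44_codebook() -> SurveyCodebook:
    """The packaged 44-item Big Five codebook with three vignettes per factor.

    Uses the published BFI-44 reverse keying, re-oriented so neuroticism
    items follow the stability-worded vignettes (and flipped back at scale
    scoring).  Override by editing a copy of the YAML or constructing a
    :class:`~avadjust.datamodel.SurveyCodebook` directly.
    """
    return SurveyCodebook.from_dict(_load("bfi44_codebook.yaml"))


def vignette_texts() -> dict:
    """English vignette texts, keyed by construct, ordered by design rank."""
    return _load("vignettes_en.yaml")
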