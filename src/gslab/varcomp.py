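"""Variance components of the progeny-trial mixed models.

The full-sib model decomposes the phenotype into additive genetic (a),
site x additive (sa), block-within-site (s(rep)), site x family (sf),
family (f) and residual (e) variance; the open-pollinated half-sib model
drops the two family terms. Narrow-sense heritability is reported with the
model-specific denominator used for these trials, which excludes the
block-within-site (experimental layout) variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["VarianceComponents", "heritability"]

_FULLSIB_TERMS = ("sigma2_a", "sigma2_sa", "sigma2_srep", "sigma2_sf", "sigma2_f", "sigma2_e")
_HALFSIB_TERMS = ("sigma2_a", "sigma2_sa", "sigma2_srep", "sigma2_e")


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components in squared trait units.

    ``sigma2_sf`` and ``sigma2_f`` are only meaningful for the full-sib
    model; leave them at 0 for half-sib analyses.
    """

    sigma2_a: float
    sigma2_sa: float = 0.0
    sigma2_srep: float = 0.0
    sigma2_sf: float = 0.0
    sigma2_f: float = 0.0
    sigma2_e: float = 0.0

    def __post_init__(self):
        for name in _FULLSIB_TERMS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def total(self, model_kind: str = "fullsib") -> float:
        """Phenotypic variance under the given model (sum of its terms)."""
        terms = _FULLSIB_TERMS if model_kind == "fullsib" else _HALFSIB_TERMS
        return float(sum(getattr(self, t) for t in terms))

    def scaled(self, factor: float) -> "VarianceComponents":
        return replace(
            self,
            **{t: getattr(self, t) * factor for t in _FULLSIB_TERMS},
        )

    def as_dict(self) -> dict:
        return {t: float(getattr(self, t)) for t in _FULLSIB_TERMS}


def heritability(vc: VarianceComponents, model_kind: str) -> float:
    """Narrow-sense heritability under the trial-specific formula.

    full-sib:  h2 = s2_a / (s2_a + s2_sa + s2_sf + s2_f + s2_e)
    half-sib:  h2 = s2_a / (s2_a + s2_sa + s2_e)

    Both denominators deliberately exclude the block-within-site variance,
    treating replication layout as experimental rather than biological noise.
    """
    if model_kind == "fullsib":
        denom = vc.sigma2_a + vc.sigma2_sa + vc.sigma2_sf + vc.sigma2_f + vc.sigma2_e
    elif model_kind == "halfsib":
        denom = vc.sigma2_a + vc.sigma2_sa + vc.sigma2_e
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if denom <= 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return float(vc.sigma2_a / denom)
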