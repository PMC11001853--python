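"""Declarative description of one competing model structure.

A structure lists the fixed-effect terms (covariate name + polynomial
degree of the standardized covariate), the count likelihood, and whether
the spatial GMRF and the cyclic month effect are included.  Every competing
model in the selection stage shares the effort offset.
"""

from __future__ import annotations

from dataclasses import dataclass

FAMILIES = ("negative_binomial", "poisson")
_FAMILY_TAG = {"negative_binomial": "nb", "poisson": "pois"}


@dataclass(frozen=True)
class ModelStructure:
    terms: tuple[tuple[str, int], ...]  # (covariate, degree <= 3)
    family: str = "negative_binomial"
    includes_spatial: bool = True
    includes_seasonal: bool = True
    offset_name: str = "offset"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("covariate repeated in structure")
        for name, deg in self.terms:
            if deg not in (1, 2, 3):
                raise ValueError(f"degree {deg} for {name!r} not in {{1, 2, 3}}")
        object.__setattr__(self, "terms", tuple((str(n), int(d)) for n, d in self.terms))

    @property
    def structure_id(self) -> str:
        parts = [f"{n}^{d}" if d > 1 else n for n, d in self.terms]
        if self.includes_spatial:
            parts.append("W")
        if self.includes_seasonal:
            parts.append("gamma(M)")
        return f"{_FAMILY_TAG[self.family]}~" + ("+".join(parts) if parts else "1")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.terms)

    def to_dict(self) -> dict:
        return {
            "terms": [[n, d] for n, d in self.terms],
            "family": self.family,
            "includes_spatial": self.includes_spatial,
            "includes_seasonal": self.includes_seasonal,
            "offset_name": self.offset_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelStructure":
        return cls(
            terms=tuple((n, int(deg)) for n, deg in d["terms"]),
            family=d.get("family", "negative_binomial"),
            includes_spatial=bool(d.get("includes_spatial", True)),
            includes_seasonal=bool(d.get("includes_seasonal", True)),
            offset_name=d.get("offset_name", "offset"),
        )
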