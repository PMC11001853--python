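"""Pre-modeling checks and enumeration of admissible model structures.

Collinear covariate pairs (Pearson |r| above a threshold, or implicated in a
generalized variance inflation factor above a threshold) are forbidden from
entering the same competing model.  Screening operates on the base
(degree-1) covariates, before polynomial expansion: the variables are
screened, not their powers.  A zero-catch fraction check advises whether a
zero-inflated likelihood would be warranted (it is a check, not a model
family here).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .structures import ModelStructure

__all__ = [
    "ScreeningReport",
    "ZeroFractionResult",
    "correlation_matrix",
    "gvif",
    "forbidden_pairs",
    "enumerate_structures",
    "zero_fraction",
    "screen",
]


def correlation_matrix(table: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations on complete cases."""
    sub = table[list(covariate_names)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    sd = sub.std(ddof=0)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance covariate(s): {list(flat.index)}")
    r = np.corrcoef(sub.to_numpy(), rowvar=False)
    return pd.DataFrame(np.atleast_2d(r), index=covariate_names, columns=covariate_names)


def gvif(table: pd.DataFrame, covariate_names: list[str]) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) per scalar covariate."""
    sub = table[list(covariate_names)].dropna().to_numpy(dtype=float)
    out = {}
    n = sub.shape[0]
    for j, name in enumerate(covariate_names):
        others = np.delete(sub, j, axis=1)
        X = np.c_[np.ones(n), others]
        y = sub[:, j]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        if r2 > 1 - 1e-12:
            raise ValueError(f"exact collinearity involving {name!r} (infinite GVIF)")
        out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class ScreeningReport:
    correlation: pd.DataFrame
    gvif: pd.Series
    forbidden: list[tuple[str, str]] = field(default_factory=list)
    zero_fraction: float | None = None

    def to_json(self, path=None) -> str:
        d = {
            "correlation": self.correlation.round(6).to_dict(),
            "gvif": self.gvif.round(6).to_dict(),
            "forbidden_pairs": [list(p) for p in self.forbidden],
            "zero_fraction": self.zero_fraction,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def forbidden_pairs(
    report: ScreeningReport, r_threshold: float = 0.6, gvif_threshold: float = 3.0
) -> list[tuple[str, str]]:
    """Covariate pairs that may not share a model structure.

    Pairs with |r| above the correlation threshold, plus — for covariates
    with GVIF above its threshold — the pair with their strongest correlation
    partner.
    """
    corr = report.correlation
    names = list(corr.index)
    pairs: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(names, 2):
        if abs(corr.loc[a, b]) > r_threshold:
            pairs.add(tuple(sorted((a, b))))
    for name, v in report.gvif.items():
        if v > gvif_threshold:
            partners = corr.loc[name].drop(name).abs()
            strongest = partners.idxmax()
            pairs.add(tuple(sorted((name, strongest))))
    return sorted(pairs)


def enumerate_structures(
    covariates: list[str],
    forbidden: list[tuple[str, str]] = (),
    degrees: tuple[int, ...] = (1, 2, 3),
    likelihoods: tuple[str, ...] = ("negative_binomial", "poisson"),
    always_in: tuple[str, ...] = ("bottom_depth",),
    include_null: bool = False,
) -> list[ModelStructure]:
    """All admissible structures: covariate subsets (no forbidden pair) x
    per-covariate polynomial degree x likelihood.

    Every structure carries the offset, the spatial field, and the cyclic
    month effect.  ``always_in`` covariates appear in every structure; the
    empty candidate subset yields an always-in-only structure (or, with no
    always-in covariates, is emitted only when ``include_null``).
    """
    if not covariates and not always_in:
        raise ValueError("no covariates to enumerate")
    forbidden_set = {tuple(sorted(p)) for p in forbidden}
    candidates = [c for c in covariates if c not in always_in]
    structures: list[ModelStructure] = []
    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            full = tuple(always_in) + subset
            if not full:
                if not include_null:
                    continue
                for fam in likelihoods:
                    structures.append(ModelStructure(terms=(), family=fam))
                continue
            if any(
                tuple(sorted((a, b))) in forbidden_set
                for a, b in itertools.combinations(full, 2)
            ):
                continue
            for degs in itertools.product(degrees, repeat=len(full)):
                for fam in likelihoods:
                    structures.append(
                        ModelStructure(terms=tuple(zip(full, degs)), family=fam)
                    )
    uniq = {s.structure_id: s for s in structures}
    return sorted(uniq.values(), key=lambda s: s.structure_id)


class ZeroFractionResult(NamedTuple):
    fraction: float
    flagged: bool
    threshold: float


def zero_fraction(sets: pd.DataFrame, threshold: float = 0.25) -> ZeroFractionResult:
    """Proportion of zero-catch sets; flags when a zero-inflated family may be needed."""
    if len(sets) == 0:
        raise ValueError("empty table")
    y = np.asarray(sets["yft_count"], dtype=float)
    frac = float(np.mean(y == 0))
    return ZeroFractionResult(frac, frac > threshold, threshold)


def screen(
    table: pd.DataFrame,
    covariate_names: list[str],
    r_threshold: float = 0.6,
    gvif_threshold: float = 3.0,
) -> ScreeningReport:
    """Full screening pass: correlations, GVIF, forbidden pairs, zero fraction."""
    report = ScreeningReport(
        correlation=correlation_matrix(table, covariate_names),
        gvif=gvif(table, covariate_names),
    )
    report.forbidden = forbidden_pairs(report, r_threshold, gvif_threshold)
    if "yft_count" in table.columns:
        report.zero_fraction = zero_fraction(table).fraction
    return report
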