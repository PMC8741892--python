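"""Decile-cutoff scan: dichotomize a continuous biomarker at each of the
nine empirical deciles, fit the mixture cure model at each cutoff, and pick
the best-fitting cutoff by minimum AIC (with likelihood-ratio p-values and
a Bonferroni adjustment across the nine tests reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    MixtureFit,
    ModelDesign,
    SurvivalRecord,
    fit,
    likelihood_ratio_test,
    select_model,
    single_covariate_designs,
)

__all__ = [
    "decile_cutoffs",
    "dichotomize",
    "DecileResult",
    "CutoffScanResult",
    "scan",
]

DECILES = (10, 20, 30, 40, 50, 60, 70, 80, 90)

#: Quantile convention used throughout (numpy's default linear interpolation,
#: the "type 7" textbook rule); recorded in output metadata.
QUANTILE_METHOD = "linear"


def decile_cutoffs(values: Sequence[float]) -> np.ndarray:
    """The nine empirical deciles (10%..90%) of a biomarker sample."""
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError(f"need at least 10 values for deciles, got {len(values)}")
    if not np.all(np.isfinite(values)):
        raise ValueError("biomarker values must be finite")
    return np.quantile(values, np.arange(1, 10) / 10.0, method=QUANTILE_METHOD)


def dichotomize(values: Sequence[float], cutoff: float) -> np.ndarray:
    """High-expression indicator: 1 where value > cutoff (ties go low)."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return (np.asarray(values, dtype=float) > cutoff).astype(int)


@dataclass
class DecileResult:
    decile: int
    cutoff: float
    fit: Optional[MixtureFit]
    ranking: Optional[pd.DataFrame]
    lrt_stat: float = np.nan
    lrt_df: int = 0
    lrt_p: float = np.nan
    failed: bool = False
    message: str = ""

    @property
    def aic(self) -> float:
        return self.fit.aic if self.fit is not None else np.nan

    @property
    def loglik(self) -> float:
        return self.fit.loglik if self.fit is not None else np.nan


@dataclass
class CutoffScanResult:
    per_decile: list[DecileResult]
    null_fit: MixtureFit
    selected_decile: int
    adjusted_p: dict[int, float] = field(default_factory=dict)
    selection_rule: str = "min-AIC"
    metadata: dict = field(default_factory=dict)

    @property
    def selected(self) -> DecileResult:
        for entry in self.per_decile:
            if entry.decile == self.selected_decile:
                return entry
        raise LookupError(f"selected decile {self.selected_decile} missing")

    def table(self) -> pd.DataFrame:
        """Per-decile summary in report order."""
        rows = []
        for e in self.per_decile:
            rows.append({
                "decile": e.decile,
                "cutoff": e.cutoff,
                "design": e.fit.design.describe() if e.fit is not None else "",
                "loglik": e.loglik,
                "aic": e.aic,
                "lrt_p": e.lrt_p,
                "lrt_p_bonferroni": self.adjusted_p.get(e.decile, np.nan),
                "selected": e.decile == self.selected_decile,
                "status": "failed: " + e.message if e.failed else "ok",
            })
        return pd.DataFrame(rows)


def _with_indicator(
    records: Sequence[SurvivalRecord], indicator: np.ndarray, name: str
) -> list[SurvivalRecord]:
    return [
        replace(r, covariates={**r.covariates, name: float(h)})
        for r, h in zip(records, indicator)
    ]


def scan(
    records: Sequence[SurvivalRecord],
    biomarker: Sequence[float],
    candidate_designs: Optional[Sequence[ModelDesign]] = None,
    covariate: str = "high",
    deciles: Sequence[int] = DECILES,
    seed: int = 0,
    min_events_per_group: int = 2,
    **fit_kwargs,
) -> CutoffScanResult:
    """Fit the mixture model at every decile cutoff and select by AIC.

    At each decile the high-expression indicator is attached as covariate
    ``covariate``, the best placement of it across the three regression
    parts is chosen by ``select_model``, and the chosen fit is compared by
    LRT to a single covariate-free null fit shared across deciles (the null
    likelihood does not depend on the cutoff).  Cutoffs leaving fewer than
    ``min_events_per_group`` events in either group are marked failed.
    Bonferroni-adjusted LRT p-values over the attempted deciles are
    reported; selection itself is by minimal AIC.
    """
    biomarker = np.asarray(biomarker, dtype=float)
    if len(biomarker) != len(records):
        raise ValueError("biomarker values must align with records")
    cutoffs = decile_cutoffs(biomarker)
    if candidate_designs is None:
        candidate_designs = single_covariate_designs(covariate)

    null_design = ModelDesign()
    null_fit = fit(records, null_design, seed=seed, **fit_kwargs)
    prefit = {null_design: null_fit}

    events = np.array([r.event for r in records], dtype=int)
    results: list[DecileResult] = []
    for decile in deciles:
        cutoff = float(cutoffs[decile // 10 - 1])
        high = dichotomize(biomarker, cutoff)
        entry = DecileResult(decile=decile, cutoff=cutoff, fit=None, ranking=None)
        ev_high = int(events[high == 1].sum())
        ev_low = int(events[high == 0].sum())
        if min(ev_high, ev_low) < min_events_per_group:
            entry.failed = True
            entry.message = (
                f"{ev_low} low-group / {ev_high} high-group events "
                f"(need >= {min_events_per_group})"
            )
            results.append(entry)
            continue
        tagged = _with_indicator(records, high, covariate)
        try:
            best, ranking = select_model(
                tagged, candidate_designs, seed=seed + decile, prefit=prefit,
                **fit_kwargs,
            )
            entry.fit = best
            entry.ranking = ranking
            entry.lrt_stat, entry.lrt_df, entry.lrt_p = likelihood_ratio_test(
                best, null_fit
            )
        except (ValueError, FloatingPointError) as exc:
            entry.failed = True
            entry.message = str(exc)
        results.append(entry)

    successes = [e for e in results if not e.failed]
    if not successes:
        raise ValueError("every decile cutoff failed")
    best_entry = min(successes, key=lambda e: (e.aic, e.fit.k, e.decile))

    m = len(deciles)
    adjusted = {
        e.decile: min(1.0, m * e.lrt_p) for e in successes if np.isfinite(e.lrt_p)
    }
    return CutoffScanResult(
        per_decile=results,
        null_fit=null_fit,
        selected_decile=best_entry.decile,
        adjusted_p=adjusted,
        metadata={
            "quantile_method": QUANTILE_METHOD,
            "tie_rule": "value > cutoff is high; ties to low",
            "adjustment": f"bonferroni (m={m})",
            "seed": seed,
        },
    )
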