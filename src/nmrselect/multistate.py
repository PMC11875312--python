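"""Correlation statistics, comparison confidence intervals, and greedy
multi-state ensemble combination.

The state-combination loop tests whether mixing candidate single-state
ensembles (equal model weights, fast-exchange assumption) improves the
concordance between the ensemble Cα RMSF and the shift-derived RMSF_RCI,
measured by Lin's concordance correlation coefficient (CCC).  Starting
from the highest-scoring candidate (state 1): if its CCC with RMSF_RCI is
not positive the search exits with a failure flag; otherwise candidates
are added greedily, each accepted addition strictly increasing the CCC,
and non-improving candidates are permanently eliminated.  A final CCC
below 0.4 flags the combination as an inadequate structural
representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import RmsfProfile, ensemble_rmsf
from .model_io import ConformerEnsemble, merge_ensembles
from .selection import CandidateEnsemble

logger = logging.getLogger("nmrselect")

CCC_ADEQUACY_THRESHOLD = 0.4
PLDDT_EXCLUDE_AT_OR_BELOW = 50.0


class MultistateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Correlation coefficients
# ---------------------------------------------------------------------------

def spearman_scc(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN ("undefined") for a constant vector; callers that need a
    number map that to 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise MultistateError("paired 1-D vectors required")
    if len(x) < 3:
        raise MultistateError("Spearman SCC needs >=3 pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2·cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))²), which
    satisfies -1 ≤ -|PCC| ≤ CCC ≤ |PCC| ≤ 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise MultistateError("paired 1-D vectors required")
    if len(x) < 3:
        raise MultistateError("Lin CCC needs >=3 pairs")
    vx = x.var()  # population (1/N) moments
    vy = y.var()
    if vx == 0 and vy == 0:
        raise MultistateError("both vectors constant: CCC undefined")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


# ---------------------------------------------------------------------------
# Comparison SEM intervals
# ---------------------------------------------------------------------------

@dataclass
class ComparisonPlotData:
    """Per-residue comparison profile with its t-based confidence band.

    ``mode="sum"`` sums RCI0.6 with pLDDT_avg/100 per residue (agreement
    plot); ``mode="difference"`` takes RMSF_RCI - RMSF_ENS.  SEM =
    SD/(N-1)^½ and CI_p = SEM · Z_p with Z_p the two-sided t critical value
    at one degree of freedom.  Residues with pLDDT ≤ 50 (or missing data)
    are excluded from N.
    """

    per_residue: pd.DataFrame  # value, outside_ci
    mode: str
    mean: float
    sd: float
    sem: float
    z_p: float
    ci_p: float
    n: int
    excluded: list[tuple[str, int]] = field(default_factory=list)


def t_critical(p: float = 0.95, df: int = 1) -> float:
    """Two-sided critical value of the t distribution (12.71 at p=95%, df=1)."""
    return float(stats.t.ppf(0.5 + p / 2.0, df))


def comparison_interval(
    a: pd.Series,
    b: pd.Series,
    mode: str = "sum",
    p: float = 0.95,
    plddt: pd.Series | None = None,
) -> ComparisonPlotData:
    """Per-residue comparison profile with mean ± CI_p flags.

    ``mode="sum"``: ``a`` is RCI0.6 and ``b`` per-residue pLDDT on the
    0-100 scale (scaled /100 before summing); residues with pLDDT ≤ 50 are
    excluded.  ``mode="difference"``: ``a - b`` (e.g. RMSF_RCI -
    RMSF_ENS); pass ``plddt`` to apply the same exclusion rule.
    """
    if mode not in ("sum", "difference"):
        raise MultistateError(f"unknown mode {mode!r}")
    common = a.index.intersection(b.index)
    excluded = [t for t in a.index.union(b.index) if t not in common]
    if mode == "sum":
        gate = b
    else:
        gate = plddt
    if gate is not None:
        low = [t for t in common if t in gate.index and gate[t] <= PLDDT_EXCLUDE_AT_OR_BELOW]
        excluded += low
        common = common.difference(pd.Index(low))
    if len(common) < 2:
        raise MultistateError(f"only {len(common)} usable residues (need >=2)")
    if mode == "sum":
        values = a.loc[common] + b.loc[common] / 100.0
    else:
        values = a.loc[common] - b.loc[common]
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    sem = sd / np.sqrt(n - 1)
    z_p = t_critical(p, df=1)
    ci = sem * z_p
    per = pd.DataFrame(
        {"value": values, "outside_ci": (values - mean).abs() > ci}
    )
    return ComparisonPlotData(
        per_residue=per, mode=mode, mean=mean, sd=sd, sem=sem,
        z_p=z_p, ci_p=ci, n=n, excluded=sorted(excluded),
    )


# ---------------------------------------------------------------------------
# Greedy state combination
# ---------------------------------------------------------------------------

@dataclass
class StateCombination:
    """Trace of the greedy multi-state assembly.

    ``accepted`` lists (candidate label, model ids) in acceptance order;
    ``ccc_trajectory`` holds the CCC after each accepted addition (strictly
    increasing); ``rejected`` pairs each eliminated candidate with the
    reason.  ``adequate`` is final CCC >= 0.4; ``failed`` marks the
    state-1 CCC <= 0 exit.
    """

    accepted: list[tuple[str, list[int]]]
    ccc_trajectory: list[float]
    rejected: list[tuple[str, str]]
    final_ccc: float
    adequate: bool
    failed: bool
    combined: ConformerEnsemble | None = None

    @property
    def n_states(self) -> int:
        return len(self.accepted)


def _ccc_vs_rci(
    ensembles: Sequence[ConformerEnsemble],
    rmsf_rci: RmsfProfile,
    align_residues,
) -> float:
    pooled = merge_ensembles("+".join(e.label for e in ensembles), ensembles)
    prof = ensemble_rmsf(pooled, align_residues)
    common = prof.values.index.intersection(rmsf_rci.values.index)
    if len(common) < 5:
        raise MultistateError(
            f"only {len(common)} residues carry both RMSF_ENS and RMSF_RCI"
        )
    return lin_ccc(
        prof.values.loc[common].to_numpy(), rmsf_rci.values.loc[common].to_numpy()
    )


def combine_states(
    candidates: Sequence[CandidateEnsemble],
    rmsf_rci: RmsfProfile,
    align_residues: Sequence[tuple[str, int]] | None = None,
) -> StateCombination:
    """Greedily assemble a multi-state ensemble maximizing CCC with RMSF_RCI.

    State 1 is the first (highest-scoring) candidate.  If its CCC with
    RMSF_RCI is not positive the search exits with ``failed=True``.
    Otherwise, each round pools the current states with every remaining
    candidate; the candidate giving the largest strictly improved CCC is
    accepted (ties by candidate rank) and every candidate that failed to
    improve in the round is permanently eliminated.
    """
    if not candidates:
        raise MultistateError("no candidate ensembles")
    state1 = candidates[0]
    current = [state1.ensemble]
    accepted = [(state1.label, list(state1.model_ids))]
    rejected: list[tuple[str, str]] = []
    ccc = _ccc_vs_rci(current, rmsf_rci, align_residues)
    if ccc <= 0:
        warnings.warn(
            f"state 1 ({state1.label}) CCC {ccc:.3f} <= 0: single-state fit "
            "fails; no combination attempted"
        )
        rejected += [(c.label, "not tested (state-1 exit)") for c in candidates[1:]]
        return StateCombination(
            accepted=accepted, ccc_trajectory=[ccc], rejected=rejected,
            final_ccc=0.0, adequate=False, failed=True,
            combined=state1.ensemble,
        )
    trajectory = [ccc]
    pool = list(candidates[1:])
    while pool:
        trials = [
            (c, _ccc_vs_rci(current + [c.ensemble], rmsf_rci, align_residues))
            for c in pool
        ]
        improving = [(c, v) for c, v in trials if v > ccc]
        for c, v in trials:
            if v <= ccc:
                rejected.append((c.label, f"CCC {v:.3f} does not improve {ccc:.3f}"))
        if not improving:
            break
        # best improvement wins; ties resolved by candidate rank (pool order)
        best_c, best_v = max(improving, key=lambda t: t[1])
        current.append(best_c.ensemble)
        accepted.append((best_c.label, list(best_c.model_ids)))
        ccc = best_v
        trajectory.append(ccc)
        pool = [c for c, v in trials if v > trajectory[-2] and c is not best_c]
    combined = merge_ensembles("+".join(lbl for lbl, _ in accepted), current)
    return StateCombination(
        accepted=accepted,
        ccc_trajectory=trajectory,
        rejected=rejected,
        final_ccc=ccc,
        adequate=ccc >= CCC_ADEQUACY_THRESHOLD,
        failed=False,
        combined=combined,
    )
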