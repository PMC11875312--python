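"""Bayesian per-model scoring against NMR data, PCA + clustering, and
candidate single-state ensemble construction.

Each conformer model is scored by
``P(model | NMR data) = (P(model|NOE) + P(model|RCI)) / 2`` where

* ``P(NOE|model)`` rescales the model's NOESY recall linearly between the
  lowest and highest recall in the scored set,
* ``P(model|NOE) = sqrt(P(NOE|model) · pTM)`` folds in the model's global
  confidence,
* ``P(model|RCI)`` combines |SCC(pLDDT, RCI)| — the rank agreement between
  the model's per-residue confidence and the shift-derived flexibility —
  with the mean pLDDT/100 (geometric mean by default; the alternative
  |SCC|·⟨pLDDT⟩^½ reading is selectable).

Models are grouped by PCA of Cα-Cα distance vectors (first three principal
components) with agglomerative clustering; the top-k models of each
cluster by P(model|NMR data) form candidate single-state ensembles, ranked
by mean score and labeled with Greek letters (the best is state 1).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import spearmanr

from .geometry import ca_distance_vector
from .model_io import ConformerEnsemble
from .noesy import MatchTolerances, PeakList, RecallReport, ShiftTable, score_recall_per_model
from .shifts import RciProfile

logger = logging.getLogger("nmrselect")

GREEK = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta")


class SelectionError(ValueError):
    pass


def _check_unit(name: str, *values: float) -> None:
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise SelectionError(f"{name} value {v} outside [0, 1]")


# ---------------------------------------------------------------------------
# Score algebra
# ---------------------------------------------------------------------------

def scale_recall(recall: float, recall_min: float, recall_max: float) -> float:
    """Min-max rescaling of NOESY recall over the scored model set.

    A degenerate set (all recalls equal) yields the uninformative 0.5.
    """
    if not (recall_min <= recall <= recall_max):
        raise SelectionError(
            f"recall {recall} outside [{recall_min}, {recall_max}]"
        )
    if recall_max == recall_min:
        warnings.warn("recall_max == recall_min: NOE likelihood uninformative (0.5)")
        return 0.5
    return (recall - recall_min) / (recall_max - recall_min)


def p_model_given_noe(p_noe_given_model: float, ptm: float) -> float:
    """Geometric mean of the scaled recall likelihood and pTM."""
    _check_unit("p_noe_given_model/ptm", p_noe_given_model, ptm)
    return math.sqrt(p_noe_given_model * ptm)


def p_model_given_rci(
    model_plddt: pd.Series,
    rci: RciProfile,
    variant: str = "geometric",
) -> float:
    """Agreement of per-residue pLDDT with shift-derived flexibility.

    SCC and ⟨pLDDT⟩ are both computed over residues where RCI exists.
    ``variant="geometric"`` gives sqrt(|SCC| · ⟨pLDDT⟩/100);
    ``variant="plddt-sqrt"`` gives |SCC| · (⟨pLDDT⟩/100)^½.  A constant
    pLDDT profile has undefined SCC and scores 0 with a warning.
    """
    if variant not in ("geometric", "plddt-sqrt"):
        raise SelectionError(f"unknown variant {variant!r}")
    common = model_plddt.index.intersection(rci.rci.index)
    if len(common) < 5:
        raise SelectionError(
            f"only {len(common)} residues have both pLDDT and RCI (need >=5)"
        )
    p = model_plddt.loc[common].to_numpy(float)
    r = rci.rci.loc[common].to_numpy(float)
    plddt_mean = float(p.mean()) / 100.0
    _check_unit("mean pLDDT/100", plddt_mean)
    if np.allclose(p, p[0]) or np.allclose(r, r[0]):
        warnings.warn("constant pLDDT or RCI profile: SCC undefined, score 0")
        return 0.0
    scc = abs(float(spearmanr(p, r).statistic))
    if variant == "geometric":
        return math.sqrt(scc * plddt_mean)
    return scc * math.sqrt(plddt_mean)


def p_model_given_nmr(p_noe: float, p_rci: float) -> float:
    """Arithmetic mean of the NOE and RCI posterior terms."""
    _check_unit("posterior term", p_noe, p_rci)
    return (p_noe + p_rci) / 2.0


@dataclass
class SelectionScore:
    """Per-model Bayesian score decomposition."""

    model_id: int
    recall: float
    p_noe_given_model: float
    ptm: float
    p_model_given_noe: float
    scc_abs: float
    plddt_mean: float  # scaled to [0, 1]
    p_model_given_rci: float
    p_model_given_nmr: float


def score_models(
    ens: ConformerEnsemble,
    peaks: PeakList | Sequence[PeakList],
    shifts: ShiftTable,
    rci: RciProfile,
    tol: MatchTolerances | None = None,
    eq9_variant: str = "geometric",
    reports: Sequence[RecallReport] | None = None,
) -> list[SelectionScore]:
    """Score every model of an ensemble against NOESY and RCI data.

    recall_min/recall_max are taken over the full model set scored in this
    run.  Precomputed per-model recall ``reports`` may be supplied to avoid
    rescoring.
    """
    if reports is None:
        reports = score_recall_per_model(peaks, shifts, ens, tol)
    if len(reports) != len(ens.models):
        raise SelectionError("one recall report per model required")
    out = []
    for m, rep in zip(ens.models, reports):
        p_noe_like = scale_recall(rep.recall, rep.recall_min, rep.recall_max)
        ptm = m.ptm if m.ptm is not None else 1.0
        p_noe = p_model_given_noe(p_noe_like, ptm)
        common = m.plddt.index.intersection(rci.rci.index)
        p = m.plddt.loc[common].to_numpy(float)
        r = rci.rci.loc[common].to_numpy(float)
        if len(common) >= 5 and not (np.allclose(p, p[0]) or np.allclose(r, r[0])):
            scc_abs = abs(float(spearmanr(p, r).statistic))
        else:
            scc_abs = 0.0
        p_rci = p_model_given_rci(m.plddt, rci, variant=eq9_variant)
        out.append(
            SelectionScore(
                model_id=m.model_id,
                recall=rep.recall,
                p_noe_given_model=p_noe_like,
                ptm=ptm,
                p_model_given_noe=p_noe,
                scc_abs=scc_abs,
                plddt_mean=float(p.mean()) / 100.0 if len(p) else 0.0,
                p_model_given_rci=p_rci,
                p_model_given_nmr=p_model_given_nmr(p_noe, p_rci),
            )
        )
    return out


def scores_to_frame(scores: Sequence[SelectionScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores]).set_index("model_id")


# ---------------------------------------------------------------------------
# PCA + clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """PCA coordinates and hierarchical-cluster labels for a model set."""

    model_ids: list[int]
    pc_coords: np.ndarray            # (n_models, n_components >= 3)
    explained_variance: np.ndarray   # fractions, non-increasing
    labels: np.ndarray               # cluster label per model (0-based)
    populations: dict[int, float]
    linkage: str
    k: int
    seed: int

    def members(self, label: int) -> list[int]:
        return [m for m, l in zip(self.model_ids, self.labels) if l == label]


def pca_cluster(
    ens: ConformerEnsemble,
    residues: Sequence[tuple[str, int]] | None = None,
    k: int = 4,
    linkage: str = "ward",
    seed: int = 0,
) -> ClusterAssignment:
    """PCA of Cα-Cα distance vectors + agglomerative clustering on PC1-3.

    Distance vectors are column-centered and decomposed by SVD; models are
    clustered on the first three principal coordinates.  Deterministic for
    fixed inputs.
    """
    n = len(ens.models)
    if k > n:
        raise SelectionError(f"k={k} exceeds model count {n}")
    x = np.stack([ca_distance_vector(m, residues) for m in ens.models])
    xc = x - x.mean(axis=0, keepdims=True)
    if k > 1 and np.allclose(xc, 0.0):
        raise SelectionError("all models identical: cannot form k>1 clusters")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    # guard against numerically-zero total variance (identical models)
    explained = var / var.sum() if var.sum() > 1e-12 else np.zeros_like(var)
    ncomp = min(3, len(s))
    coords = u[:, :ncomp] * s[:ncomp]
    if coords.shape[1] < 3:  # degenerate rank: pad for a stable interface
        coords = np.pad(coords, ((0, 0), (0, 3 - coords.shape[1])))
    if k == 1:
        labels = np.zeros(n, int)
    else:
        z = scipy_linkage(coords[:, :3], method=linkage)
        labels = fcluster(z, t=k, criterion="maxclust") - 1
    pops = {int(l): float((labels == l).sum()) / n for l in np.unique(labels)}
    return ClusterAssignment(
        model_ids=[m.model_id for m in ens.models],
        pc_coords=coords,
        explained_variance=explained[: len(s)],
        labels=labels,
        populations=pops,
        linkage=linkage,
        k=k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Candidate single-state ensembles
# ---------------------------------------------------------------------------

@dataclass
class CandidateEnsemble:
    """A cluster's top-k models as a candidate conformational state."""

    label: str            # e.g. "alpha5"
    cluster: int
    ensemble: ConformerEnsemble
    model_ids: list[int]
    mean_score: float


def build_candidate_ensembles(
    assignment: ClusterAssignment,
    scores: Sequence[SelectionScore],
    ens: ConformerEnsemble,
    k_top: int = 5,
) -> list[CandidateEnsemble]:
    """Top-``k_top`` models per cluster, ranked by mean P(model|NMR data).

    Ties break by higher pTM, then lower model id.  Clusters smaller than
    ``k_top`` contribute all their members with a warning.  Candidates are
    labeled alpha/beta/gamma/delta... in descending mean score; the first
    is state 1.
    """
    by_id = {s.model_id: s for s in scores}
    candidates = []
    for label in sorted(set(assignment.labels)):
        members = assignment.members(int(label))
        if len(members) < k_top:
            warnings.warn(
                f"cluster {label} has only {len(members)} models (< k_top={k_top})"
            )
        ranked = sorted(
            members,
            key=lambda m: (-by_id[m].p_model_given_nmr, -by_id[m].ptm, m),
        )[:k_top]
        mean_score = float(np.mean([by_id[m].p_model_given_nmr for m in ranked]))
        candidates.append((int(label), ranked, mean_score))
    candidates.sort(key=lambda t: -t[2])
    out = []
    for rank, (cluster, ids, mean_score) in enumerate(candidates):
        greek = GREEK[rank] if rank < len(GREEK) else f"state{rank + 1}"
        name = f"{greek}{len(ids)}"
        out.append(
            CandidateEnsemble(
                label=name,
                cluster=cluster,
                ensemble=ens.subset(ids, label=name),
                model_ids=ids,
                mean_score=mean_score,
            )
        )
    return out
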