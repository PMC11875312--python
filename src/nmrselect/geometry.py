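"""Superposition, ensemble RMSF, distance features, TM-score, and sanity checks.

All comparisons assume the structures share residue numbering (no sequence
alignment is performed).  Per-residue profiles are pandas Series indexed by
``(chain, resnum)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .model_io import ConformerEnsemble, ConformerModel

logger = logging.getLogger("nmrselect")


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RmsfProfile:
    """Per-residue root-mean-square fluctuation in Å.

    ``source`` is ``"ensemble"`` (coordinate spread about the ensemble mean)
    or ``"rci"`` (estimated from chemical shifts).
    """

    values: pd.Series  # index (chain, resnum), Å
    source: str

    def __post_init__(self) -> None:
        if self.source not in ("ensemble", "rci"):
            raise GeometryError(f"unknown RMSF source {self.source!r}")
        if len(self.values) and (self.values < 0).any():
            raise GeometryError("negative RMSF")

    def residues(self) -> list[tuple[str, int]]:
        return list(self.values.index)


@dataclass
class SanityReport:
    """Physical-plausibility flags per model; verdict fails iff any flag set."""

    d_chirality: dict[int, list[tuple[str, int]]] = field(default_factory=dict)
    cis_peptides: dict[int, list[tuple[str, int]]] = field(default_factory=dict)
    missing_backbone: dict[int, list[tuple[str, int]]] = field(default_factory=dict)

    def flagged_models(self) -> set[int]:
        out = set()
        for d in (self.d_chirality, self.cis_peptides, self.missing_backbone):
            out.update(k for k, v in d.items() if v)
        return out

    def verdict(self, model_id: int) -> str:
        return "fail" if model_id in self.flagged_models() else "pass"


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose_kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of matched coordinate sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference.
    The rotation is proper (determinant +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("superposition needs matched (n, 3) coordinate sets")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs >=3 matched pairs, got {n}")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    p, q = mobile - mc, reference - rc
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) coordinate configuration")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    diff = (mobile @ rot.T + trans) - reference
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return rot, trans, rmsd


def _masked_ca(
    model: ConformerModel, residues: Sequence[tuple[str, int]]
) -> np.ndarray:
    missing = [(c, r) for c, r in residues if not model.has_atom(c, r, "CA")]
    if missing:
        raise GeometryError(f"model {model.model_id}: missing CA for {missing}")
    return model.ca_coords(residues)


def apply_rigid(model: ConformerModel, rot: np.ndarray, trans: np.ndarray) -> ConformerModel:
    """Return a copy of the model with all atoms rigidly transformed."""
    atoms = model.atoms.copy()
    xyz = atoms[["x", "y", "z"]].to_numpy(float) @ rot.T + trans
    atoms[["x", "y", "z"]] = xyz
    return ConformerModel(model.model_id, atoms, model.plddt, model.ptm)


# ---------------------------------------------------------------------------
# Ensemble RMSF
# ---------------------------------------------------------------------------

def ensemble_rmsf(
    ens: ConformerEnsemble,
    align_residues: Sequence[tuple[str, int]] | None = None,
) -> RmsfProfile:
    """Per-residue Cα RMSF about the iterative ensemble mean structure.

    Each model is superposed (Kabsch, over ``align_residues``) onto the mean
    Cα structure; the mean is then recomputed and the superposition repeated
    once more, which removes the dependence on model order.  Residues
    without a Cα in every model are excluded.
    """
    residues = [
        (c, r)
        for c, r, _ in ens.residues()
        if all(m.has_atom(c, r, "CA") for m in ens.models)
    ]
    if align_residues is None:
        align = residues
    else:
        align = [t for t in align_residues if t in set(residues)]
        if len(align) < 3:
            raise GeometryError("fewer than 3 alignable residues")
    if len(ens) == 1:
        warnings.warn("single-model ensemble: RMSF is identically zero")
        vals = pd.Series(0.0, index=pd.MultiIndex.from_tuples(residues))
        return RmsfProfile(values=vals, source="ensemble")

    coords = np.stack([_masked_ca(m, residues) for m in ens.models])  # (M, L, 3)
    ai = [residues.index(t) for t in align]
    # initial alignment onto the first model removes each input's arbitrary
    # frame, making the result invariant under rigid motion of any model
    aligned0 = []
    for x in coords:
        rot, trans, _ = superpose_kabsch(x[ai], coords[0][ai])
        aligned0.append(x @ rot.T + trans)
    coords = np.stack(aligned0)
    mean = coords.mean(axis=0)
    for _ in range(2):  # two alignment passes onto the running mean
        aligned = []
        for x in coords:
            rot, trans, _ = superpose_kabsch(x[ai], mean[ai])
            aligned.append(x @ rot.T + trans)
        coords = np.stack(aligned)
        mean = coords.mean(axis=0)
    dev = coords - mean
    rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    vals = pd.Series(rmsf, index=pd.MultiIndex.from_tuples(residues))
    return RmsfProfile(values=vals, source="ensemble")


# ---------------------------------------------------------------------------
# Cα-Cα distance features
# ---------------------------------------------------------------------------

def ca_distance_vector(
    model: ConformerModel, residues: Sequence[tuple[str, int]] | None = None
) -> np.ndarray:
    """Flattened upper-triangular (i<j, row-major) Cα-Cα distance matrix."""
    if residues is None:
        residues = [(c, r) for c, r, _ in model.residues()]
    missing = [t for t in residues if not model.has_atom(*t, "CA")]
    if missing:
        raise GeometryError(f"model {model.model_id}: missing CA for {missing}")
    return pdist(model.ca_coords(residues))


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(length: int) -> float:
    """TM-score normalization distance, floored at 0.5 Å."""
    if length <= 15:
        warnings.warn(f"TM-score of only {length} residues: d0 floored at 0.5")
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_superposition(
    mob: np.ndarray, ref: np.ndarray, seed_idx: np.ndarray, d0: float
) -> float:
    """TM-score after iterative-extension refinement starting from a seed."""
    idx = seed_idx
    best = 0.0
    for _ in range(20):
        try:
            rot, trans, _ = superpose_kabsch(mob[idx], ref[idx])
        except GeometryError:
            break
        d = np.linalg.norm(mob @ rot.T + trans - ref, axis=1)
        score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
        best = max(best, score)
        new_idx = np.where(d < max(d0, 3.0))[0]
        if len(new_idx) < 3 or np.array_equal(new_idx, idx):
            break
        idx = new_idx
    return best


def tm_score(
    model: ConformerModel,
    reference: ConformerModel,
    residues: Sequence[tuple[str, int]] | None = None,
    seed_step: int | None = None,
) -> float:
    """TM-score of ``model`` against ``reference`` over shared residues.

    Uses d0(L) = 1.24·(L-15)^(1/3) - 1.8 (floored at 0.5 Å), maximized over
    contiguous seed fragments of several lengths with iterative extension;
    normalized by the aligned length (the reference coverage).
    """
    if residues is None:
        residues = [(c, r) for c, r, _ in reference.residues()]
    mob = _masked_ca(model, residues)
    ref = _masked_ca(reference, residues)
    L = len(residues)
    d0 = tm_d0(L)
    step = seed_step or max(1, L // 10)
    lengths = sorted({L, max(4, L // 2), max(4, L // 4), 4})
    best = 0.0
    for ln in lengths:
        for start in range(0, L - ln + 1, step):
            seed = np.arange(start, start + ln)
            best = max(best, _tm_from_superposition(mob, ref, seed, d0))
    return min(1.0, best)


# ---------------------------------------------------------------------------
# Well-defined ranges
# ---------------------------------------------------------------------------

def parse_ranges(text: str) -> list[tuple[int, int]]:
    """Parse ``"start-end[,start-end...]"`` (1-based, inclusive)."""
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        a, _, b = part.partition("-")
        out.append((int(a), int(b or a)))
    return out


def format_ranges(ranges: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{a}-{b}" for a, b in ranges)


def ranges_from_rmsf(
    profile: RmsfProfile, rmsf_cutoff: float = 2.0
) -> list[tuple[int, int]]:
    """Merge residues with RMSF ≤ cutoff into well-defined ranges.

    Gaps of ≤2 residues are bridged; ranges shorter than 4 residues are
    dropped.  Works for either RMSF source — the ensemble spread or the
    shift-derived (RCI) estimate, the latter picking the experimentally
    rigid core without reference to any model.
    """
    ok = sorted(r for (_, r), v in profile.values.items() if v <= rmsf_cutoff)
    if not ok:
        warnings.warn("no residue passes the well-defined RMSF cutoff")
        return []
    ranges: list[list[int]] = [[ok[0], ok[0]]]
    for r in ok[1:]:
        if r - ranges[-1][1] <= 3:  # gap of <=2 missing residues bridged
            ranges[-1][1] = r
        else:
            ranges.append([r, r])
    kept = [(a, b) for a, b in ranges if b - a + 1 >= 4]
    if not kept:
        warnings.warn("all well-defined ranges shorter than 4 residues; none kept")
    return kept


def well_defined_ranges(
    ens: ConformerEnsemble,
    rmsf_cutoff: float = 2.0,
    override: Sequence[tuple[int, int]] | str | None = None,
) -> list[tuple[int, int]]:
    """Low-RMSF residue ranges used for superposition and scoring.

    Residues with ensemble RMSF ≤ ``rmsf_cutoff`` (after global
    superposition) are merged into ranges; gaps of ≤2 residues are bridged
    and ranges shorter than 4 residues dropped.  A user-supplied
    ``override`` is returned verbatim.
    """
    if override is not None:
        return parse_ranges(override) if isinstance(override, str) else list(override)
    return ranges_from_rmsf(ensemble_rmsf(ens), rmsf_cutoff)


def residues_in_ranges(
    ens: ConformerEnsemble, ranges: Sequence[tuple[int, int]]
) -> list[tuple[str, int]]:
    keep = [
        (c, r)
        for c, r, _ in ens.residues()
        if any(a <= r <= b for a, b in ranges)
    ]
    return keep


def medoid_model(
    ens: ConformerEnsemble, residues: Sequence[tuple[str, int]] | None = None
) -> ConformerModel:
    """Model with minimum summed pairwise Cα RMSD over the given residues."""
    if residues is None:
        residues = ens.residue_keys()
    coords = [_masked_ca(m, residues) for m in ens.models]
    n = len(coords)
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = superpose_kabsch(coords[i], coords[j])
            total[i] += rmsd
            total[j] += rmsd
    return ens.models[int(np.argmin(total))]


# ---------------------------------------------------------------------------
# Physical-sanity filtering
# ---------------------------------------------------------------------------

BACKBONE = ("N", "CA", "C")


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def chirality_volume(model: ConformerModel, chain: str, resnum: int) -> float | None:
    """Signed triple product (N-CA) x (C-CA) · (CB-CA); positive for L-residues."""
    try:
        n = model.coord(chain, resnum, "N")
        ca = model.coord(chain, resnum, "CA")
        c = model.coord(chain, resnum, "C")
        cb = model.coord(chain, resnum, "CB")
    except KeyError:
        return None
    return float(np.dot(np.cross(n - ca, c - ca), cb - ca))


def sanity_filter(
    ens: ConformerEnsemble,
    cis_omega_cutoff: float = 30.0,
) -> tuple[ConformerEnsemble, SanityReport]:
    """Drop physically unreasonable models.

    Flags (a) D-amino-acid chirality via the sign of the Cα improper
    (N, C, Cβ) triple product, (b) cis peptide bonds (|ω| < 30°) preceding
    non-proline residues, and (c) missing backbone atoms.  Flagged models
    are removed; an error is raised if nothing survives.
    """
    report = SanityReport()
    residues = ens.residues()
    for m in ens.models:
        chir, cis, missing = [], [], []
        for c, r, name in residues:
            for a in BACKBONE:
                if not m.has_atom(c, r, a):
                    missing.append((c, r))
                    break
        for c, r, name in residues:
            if name == "GLY":
                continue
            vol = chirality_volume(m, c, r)
            if vol is not None and vol < 0:
                chir.append((c, r))
        for (c1, r1, n1), (c2, r2, n2) in zip(residues, residues[1:]):
            if c1 != c2 or r2 != r1 + 1 or n2 == "PRO":
                continue
            try:
                omega = _dihedral(
                    m.coord(c1, r1, "CA"), m.coord(c1, r1, "C"),
                    m.coord(c2, r2, "N"), m.coord(c2, r2, "CA"),
                )
            except KeyError:
                continue
            if abs(omega) < cis_omega_cutoff:
                cis.append((c2, r2))
        report.d_chirality[m.model_id] = chir
        report.cis_peptides[m.model_id] = cis
        report.missing_backbone[m.model_id] = missing

    bad = report.flagged_models()
    keep = [m for m in ens.models if m.model_id not in bad]
    if not keep:
        raise GeometryError("sanity filter removed every model")
    if bad:
        logger.info("sanity filter removed %d/%d models", len(bad), len(ens))
    return ConformerEnsemble(ens.label, keep), report
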