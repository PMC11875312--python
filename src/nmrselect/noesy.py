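"""NOESY peak matching, recall/precision/F scoring, Double Recall, and
peak back-calculation.

A 3D NOESY peak (w_Hdonor, w_X, w_Hacceptor) is matched against the shift
table: candidate donor protons must match w_Hdonor within the proton
tolerance and their covalently bonded heavy atom (of the spectrum's
isotope) must match w_X; candidate acceptors match w_Hacceptor.  A peak is
*explained* by an ensemble when any candidate pair's summarized interproton
distance is within the cutoff.  Equivalent protons (methyls, degenerate
aromatic ring pairs, geminal pairs sharing one assignment) are treated as
groups, with the minimum distance over group members by default.

Double Recall compares the explained-peak sets of two ensembles built from
identical peak lists, isolating NOEs uniquely explained by each — the
cross-validation step for proposed multi-state models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import ConformerEnsemble, ConformerModel, PeakList, ShiftTable

logger = logging.getLogger("nmrselect")

LONG_RANGE_SEP = 5  # |i - j| >= 5 is "long range" by NMR convention


class NoesyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tolerances
# ---------------------------------------------------------------------------

@dataclass
class MatchTolerances:
    """Frequency-match tolerances (ppm), distance cutoff (Å), and the
    across-model distance summarizer."""

    h_ppm: float = 0.05
    c_ppm: float = 0.4
    n_ppm: float = 0.5
    distance_cutoff: float = 5.0
    ensemble_summarizer: str = "midrange"  # per_model | min | midrange | median
    equivalent_method: str = "min"  # min | r6sum

    def __post_init__(self) -> None:
        if min(self.h_ppm, self.c_ppm, self.n_ppm, self.distance_cutoff) <= 0:
            raise NoesyError("tolerances and cutoff must be positive")
        if self.distance_cutoff > 6.5:
            raise NoesyError("distance cutoff above 6.5 Å is not NOE-observable")
        if self.ensemble_summarizer not in ("per_model", "min", "midrange", "median"):
            raise NoesyError(f"unknown summarizer {self.ensemble_summarizer!r}")
        if self.equivalent_method not in ("min", "r6sum"):
            raise NoesyError(f"unknown equivalent-proton method {self.equivalent_method!r}")

    def x_ppm(self, heavy_element: str) -> float:
        return self.n_ppm if heavy_element == "N" else self.c_ppm


# ---------------------------------------------------------------------------
# Proton groups
# ---------------------------------------------------------------------------

_RING_GROUPS = {("PHE", "HD"), ("PHE", "HE"), ("TYR", "HD"), ("TYR", "HE")}


def _heavy_candidates(proton: str) -> list[str]:
    """Possible covalently bonded heavy-atom names for a proton name."""
    if proton in ("H", "HN"):
        return ["N"]
    rest = proton[1:]
    out = []
    for base in (rest, rest[:-1] if rest and rest[-1].isdigit() else None):
        if base:
            out += ["C" + base, "N" + base, "O" + base]
    return out or ["CA"]


@dataclass
class ProtonGroup:
    """An equivalence class of protons sharing one assigned shift."""

    chain: str
    resnum: int
    restype: str
    key: str                 # e.g. "H", "HA", "HB" (methyl), "QD" (ring)
    proton_shift: float
    heavy_atom: str | None   # representative bonded heavy atom
    heavy_shift: float | None
    heavy_element: str | None
    atom_names: tuple[str, ...]  # shift-table proton names in the group

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.resnum}:{self.key}"

    def model_protons(self, model: ConformerModel) -> list[str]:
        """Expand to proton atom names present in the model.

        A name absent from the model is pseudo-expanded with numeric
        suffixes (a methyl assigned as one ``HB`` entry expands to
        HB1/HB2/HB3).
        """
        out = []
        for name in self.atom_names:
            if model.has_atom(self.chain, self.resnum, name):
                out.append(name)
            else:
                out.extend(
                    f"{name}{i}"
                    for i in (1, 2, 3)
                    if model.has_atom(self.chain, self.resnum, f"{name}{i}")
                )
        return out


def _group_key(restype: str, proton: str) -> str:
    """Equivalence-group key for a proton name."""
    base = proton[:-1] if proton[-1:].isdigit() else proton
    if (restype, base) in _RING_GROUPS:
        return "Q" + base[1:]  # HD1/HD2 -> QD (degenerate ring pair)
    if base in ("H", "HN"):
        return "H"
    return base  # HB1/HB2/HB3 -> HB; HA2/HA3 -> HA; HA -> HA


def build_proton_groups(shifts: ShiftTable) -> list[ProtonGroup]:
    """Collapse the shift table's proton entries into equivalence groups."""
    buckets: dict[tuple, list] = {}
    for row in shifts.entries.itertuples(index=False):
        if not row.atom.startswith("H"):
            continue
        key = _group_key(row.restype, row.atom)
        buckets.setdefault((row.chain, int(row.resnum), row.restype, key), []).append(row)
    groups = []
    for (chain, resnum, restype, key), rows in sorted(buckets.items()):
        heavy = heavy_shift = element = None
        for row in rows:
            for cand in _heavy_candidates(row.atom):
                s = shifts.get(chain, resnum, cand)
                if s is not None:
                    heavy, heavy_shift, element = cand, s, cand[0]
                    break
            if heavy:
                break
        if heavy is None:
            # no assigned heavy shift: still usable as acceptor; remember
            # the structurally bonded heavy atom for pseudo-atom fallback
            heavy = _heavy_candidates(rows[0].atom)[0]
            element = heavy[0]
        groups.append(
            ProtonGroup(
                chain=chain,
                resnum=resnum,
                restype=restype,
                key=key,
                proton_shift=float(np.mean([r.shift for r in rows])),
                heavy_atom=heavy,
                heavy_shift=heavy_shift,
                heavy_element=element,
                atom_names=tuple(r.atom for r in rows),
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _group_coords(model: ConformerModel, g: ProtonGroup) -> tuple[np.ndarray, float]:
    """Coordinates of the group's protons in a model.

    Returns ``(coords, correction)``; when the model carries no protons for
    the group, the bonded heavy atom serves as a pseudo-atom with a 1.0 Å
    distance correction.
    """
    names = g.model_protons(model)
    if names:
        return (
            np.array([model.coord(g.chain, g.resnum, n) for n in names]),
            0.0,
        )
    if g.heavy_atom and model.has_atom(g.chain, g.resnum, g.heavy_atom):
        return model.coord(g.chain, g.resnum, g.heavy_atom)[None, :], 1.0
    raise NoesyError(
        f"model {model.model_id}: no protons or heavy atom for group {g.label}"
    )


def model_pair_distance(
    model: ConformerModel,
    pair: tuple[ProtonGroup, ProtonGroup],
    method: str = "min",
    _cache: dict | None = None,
) -> float:
    """Interproton distance of a group pair in one model.

    ``min`` takes the minimum over equivalent-proton expansions; ``r6sum``
    the NOE-intensity-weighted (Σ r⁻⁶)^(-1/6) effective distance.
    """
    g1, g2 = pair

    def coords(g: ProtonGroup):
        if _cache is None:
            return _group_coords(model, g)
        key = (id(model), g.label)
        if key not in _cache:
            _cache[key] = _group_coords(model, g)
        return _cache[key]

    c1, corr1 = coords(g1)
    c2, corr2 = coords(g2)
    if corr1 or corr2:
        warnings.warn(
            f"pseudo-atom fallback for {g1.label}/{g2.label} "
            f"(model without protons); applying 1.0 Å correction"
        )
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=2).ravel()
    if method == "r6sum":
        eff = float((d**-6).sum() ** (-1.0 / 6.0))
    else:
        eff = float(d.min())
    return max(0.0, eff - corr1 - corr2)


def _summarize(per_model: np.ndarray, summarizer: str):
    if summarizer == "per_model":
        return per_model
    if summarizer == "min":
        return float(per_model.min())
    if summarizer == "midrange":
        return float((per_model.min() + per_model.max()) / 2.0)
    return float(np.median(per_model))


def ensemble_pair_distance(
    ens: ConformerEnsemble | Sequence[ConformerEnsemble],
    pair: tuple[ProtonGroup, ProtonGroup],
    tol: MatchTolerances,
    _cache: dict | None = None,
):
    """Summarized interproton distance of a pair across an ensemble.

    For a list of ensembles (conformational states), per-state summaries are
    merged with the minimum rule: an NOE is explainable if *any* state
    brings the pair close.
    """
    if isinstance(ens, ConformerEnsemble):
        per_model = np.array(
            [
                model_pair_distance(m, pair, tol.equivalent_method, _cache=_cache)
                for m in ens.models
            ]
        )
        return _summarize(per_model, tol.ensemble_summarizer)
    summaries = [ensemble_pair_distance(e, pair, tol, _cache=_cache) for e in ens]
    return min(summaries)


# ---------------------------------------------------------------------------
# Peak matching
# ---------------------------------------------------------------------------

def match_peaks(
    peaks: PeakList, shifts: ShiftTable, tol: MatchTolerances
) -> list[list[tuple[ProtonGroup, ProtonGroup]]]:
    """Candidate (donor, acceptor) proton-group pairs for every peak.

    Donors must carry the spectrum's heavy isotope with an assigned heavy
    shift; the donor and acceptor may not be the same equivalence group
    (diagonal peaks).  An empty candidate list marks an unmatched peak.
    """
    groups = build_proton_groups(shifts)
    donors = [
        g for g in groups
        if g.heavy_element == peaks.heavy_element and g.heavy_shift is not None
    ]
    if not groups:
        raise NoesyError("shift table contains no assigned protons")
    tol_x = tol.x_ppm(peaks.heavy_element)
    dh = np.array([g.proton_shift for g in donors])
    dx = np.array([g.heavy_shift for g in donors])
    ah = np.array([g.proton_shift for g in groups])
    out = []
    for row in peaks.peaks.itertuples(index=False):
        if len(donors):
            dsel = np.where(
                (np.abs(dh - row.w_hdonor) <= tol.h_ppm)
                & (np.abs(dx - row.w_x) <= tol_x)
            )[0]
        else:
            dsel = np.array([], int)
        asel = np.where(np.abs(ah - row.w_hacceptor) <= tol.h_ppm)[0]
        cands = [
            (donors[i], groups[j])
            for i in dsel
            for j in asel
            if donors[i].label != groups[j].label
        ]
        out.append(cands)
    return out


def match_peak(
    peak_row, peaks: PeakList, shifts: ShiftTable, tol: MatchTolerances
) -> list[tuple[ProtonGroup, ProtonGroup]]:
    """Candidates for a single peak id (convenience wrapper)."""
    idx = peaks.peaks.index[peaks.peaks["peak_id"] == peak_row].tolist()
    if not idx:
        raise NoesyError(f"no peak with id {peak_row}")
    sub = PeakList(peaks.spectrum_type, peaks.peaks.loc[idx].reset_index(drop=True))
    return match_peaks(sub, shifts, tol)[0]


# ---------------------------------------------------------------------------
# Recall / precision / F
# ---------------------------------------------------------------------------

@dataclass
class RecallReport:
    """Per-peak explanation status and aggregate recall/precision/F.

    ``peak_table`` columns: spectrum, peak_id, status (explained /
    unexplained / unmatched), donor, acceptor, donor_resnum,
    acceptor_resnum, distance.
    """

    peak_table: pd.DataFrame
    recall: float
    precision: float
    f_measure: float
    ensemble_label: str
    recall_min: float | None = None
    recall_max: float | None = None

    def explained_keys(self) -> set[tuple[str, int]]:
        t = self.peak_table
        return set(
            zip(t.loc[t.status == "explained", "spectrum"],
                t.loc[t.status == "explained", "peak_id"])
        )

    def peak_universe(self) -> set[tuple[str, int]]:
        return set(zip(self.peak_table["spectrum"], self.peak_table["peak_id"]))


def _as_peak_lists(peaks) -> list[PeakList]:
    return [peaks] if isinstance(peaks, PeakList) else list(peaks)


def score_recall(
    peaks: PeakList | Sequence[PeakList],
    shifts: ShiftTable,
    ens: ConformerEnsemble | Sequence[ConformerEnsemble],
    tol: MatchTolerances | None = None,
) -> RecallReport:
    """Score an ensemble (or merged set of states) against NOESY peak lists.

    A peak is explained when any candidate pair's summarized distance is
    within the cutoff.  Precision is the fraction of short (≤ cutoff)
    inter-residue interproton distances among observable assigned pairs
    that are supported by at least one matching peak; F is the harmonic
    mean of recall and precision.
    """
    tol = tol or MatchTolerances()
    peak_lists = _as_peak_lists(peaks)
    if not peak_lists or any(len(p) == 0 for p in peak_lists):
        raise NoesyError("empty peak list")
    label = ens.label if isinstance(ens, ConformerEnsemble) else "+".join(
        e.label for e in ens
    )

    dist_cache: dict[tuple[str, str], float] = {}
    coord_cache: dict = {}

    def pair_distance(g1: ProtonGroup, g2: ProtonGroup) -> float:
        key = (g1.label, g2.label)
        if key not in dist_cache:
            d = ensemble_pair_distance(ens, (g1, g2), tol, _cache=coord_cache)
            dist_cache[key] = d
            dist_cache[(key[1], key[0])] = d
        return dist_cache[key]

    rows = []
    supported: set[tuple[str, str]] = set()
    observable_pairs: dict[tuple[str, str], tuple[ProtonGroup, ProtonGroup]] = {}
    for plist in peak_lists:
        cands = match_peaks(plist, shifts, tol)
        groups = build_proton_groups(shifts)
        donors = [
            g for g in groups
            if g.heavy_element == plist.heavy_element and g.heavy_shift is not None
        ]
        for d in donors:
            for a in groups:
                if d.label == a.label:
                    continue
                if d.chain == a.chain and abs(d.resnum - a.resnum) < 1:
                    continue  # intra-residue pairs excluded from precision
                observable_pairs.setdefault((d.label, a.label), (d, a))
        for row, cand in zip(plist.peaks.itertuples(index=False), cands):
            if not cand:
                rows.append(
                    (plist.spectrum_type, row.peak_id, "unmatched",
                     None, None, None, None, np.nan)
                )
                continue
            dists = [pair_distance(g1, g2) for g1, g2 in cand]
            best = int(np.argmin(dists))
            g1, g2 = cand[best]
            status = "explained" if dists[best] <= tol.distance_cutoff else "unexplained"
            if status == "explained":
                for c1, c2 in cand:  # every matching short pair is supported
                    if pair_distance(c1, c2) <= tol.distance_cutoff:
                        supported.add((c1.label, c2.label))
            rows.append(
                (plist.spectrum_type, row.peak_id, status,
                 g1.label, g2.label, g1.resnum, g2.resnum, dists[best])
            )

    table = pd.DataFrame(
        rows,
        columns=["spectrum", "peak_id", "status", "donor", "acceptor",
                 "donor_resnum", "acceptor_resnum", "distance"],
    )
    n = len(table)
    n_explained = int((table.status == "explained").sum())
    recall = n_explained / n

    short = [
        key for key, pair in observable_pairs.items()
        if pair_distance(*pair) <= tol.distance_cutoff
    ]
    precision = (
        len([k for k in short if k in supported]) / len(short) if short else 0.0
    )
    f = (
        2 * recall * precision / (recall + precision)
        if (recall + precision) > 0
        else 0.0
    )
    return RecallReport(
        peak_table=table, recall=recall, precision=precision, f_measure=f,
        ensemble_label=label,
    )


def score_recall_per_model(
    peaks: PeakList | Sequence[PeakList],
    shifts: ShiftTable,
    ens: ConformerEnsemble,
    tol: MatchTolerances | None = None,
) -> list[RecallReport]:
    """Per-model recall reports with the set-wide recall_min/recall_max."""
    tol = tol or MatchTolerances()
    reports = []
    for m in ens.models:
        single = ConformerEnsemble(f"{ens.label}/m{m.model_id}", [m])
        reports.append(score_recall(peaks, shifts, single, tol))
    recalls = [r.recall for r in reports]
    lo, hi = min(recalls), max(recalls)
    for r in reports:
        r.recall_min, r.recall_max = lo, hi
    return reports


# ---------------------------------------------------------------------------
# Double Recall
# ---------------------------------------------------------------------------

@dataclass
class DoubleRecallResult:
    """NOEs uniquely explained by each of two ensembles, plus shared NOEs.

    ``contacts`` collapses multiple NOEs between one residue pair into a
    single row (res_i = donor residue, res_j = acceptor residue);
    ``histogram`` counts unique peaks per donor residue; long-range means
    sequence separation >= 5.
    """

    unique_to_a: set[tuple[str, int]]
    unique_to_b: set[tuple[str, int]]
    shared: set[tuple[str, int]]
    label_a: str
    label_b: str
    contacts: pd.DataFrame     # res_i, res_j, set, count
    histogram: pd.DataFrame    # resnum, set, count
    long_range_a: set[tuple[str, int]] = field(default_factory=set)
    long_range_b: set[tuple[str, int]] = field(default_factory=set)


def double_recall(report_a: RecallReport, report_b: RecallReport) -> DoubleRecallResult:
    """Partition explained NOEs into unique-to-A, unique-to-B, and shared."""
    if report_a.peak_universe() != report_b.peak_universe():
        raise NoesyError("Double Recall requires identical peak lists")
    ea, eb = report_a.explained_keys(), report_b.explained_keys()
    ua, ub, shared = ea - eb, eb - ea, ea & eb

    def _pairs(report: RecallReport, keys: set) -> pd.DataFrame:
        t = report.peak_table
        mask = [
            (s, p) in keys for s, p in zip(t["spectrum"], t["peak_id"])
        ]
        return t[mask]

    contact_rows, hist_rows = [], []
    lr = {}
    for name, keys, rep in (
        ("unique_A", ua, report_a),
        ("unique_B", ub, report_b),
        ("shared", shared, report_a),
    ):
        sub = _pairs(rep, keys)
        lr[name] = {
            (s, p)
            for s, p, i, j in zip(sub["spectrum"], sub["peak_id"],
                                  sub["donor_resnum"], sub["acceptor_resnum"])
            if abs(int(i) - int(j)) >= LONG_RANGE_SEP
        }
        grouped = sub.groupby(["donor_resnum", "acceptor_resnum"]).size()
        for (i, j), cnt in grouped.items():
            contact_rows.append((int(i), int(j), name, int(cnt)))
        for i, cnt in sub.groupby("donor_resnum").size().items():
            hist_rows.append((int(i), name, int(cnt)))

    return DoubleRecallResult(
        unique_to_a=ua, unique_to_b=ub, shared=shared,
        label_a=report_a.ensemble_label, label_b=report_b.ensemble_label,
        contacts=pd.DataFrame(contact_rows, columns=["res_i", "res_j", "set", "count"]),
        histogram=pd.DataFrame(hist_rows, columns=["resnum", "set", "count"]),
        long_range_a=lr["unique_A"], long_range_b=lr["unique_B"],
    )


# ---------------------------------------------------------------------------
# Peak back-calculation
# ---------------------------------------------------------------------------

def simulate_peaks(
    ens: ConformerEnsemble | Sequence[ConformerEnsemble],
    shifts: ShiftTable,
    tol: MatchTolerances | None = None,
    spectrum_type: str = "N15-NOESY",
    jitter: float = 0.0,
    seed: int | None = None,
) -> tuple[PeakList, dict]:
    """Back-calculate a NOESY peak list from an ensemble (or merged states).

    One peak per ordered (donor, acceptor) proton-group pair whose
    summarized distance is within the cutoff; the donor must carry the
    spectrum's isotope with an assigned heavy shift.  Peaks sit at the
    assigned frequencies plus optional Gaussian jitter (ppm, seeded).
    Pairs skipped for missing assignments are tallied in the skip report.
    """
    tol = tol or MatchTolerances()
    rng = np.random.default_rng(seed)
    groups = build_proton_groups(shifts)
    heavy_el = "N" if spectrum_type == "N15-NOESY" else "C"
    donors = [g for g in groups if g.heavy_element == heavy_el]
    skip = {"donor_without_heavy_shift": 0, "pairs_beyond_cutoff": 0}
    coord_cache: dict = {}
    rows = []
    for d in donors:
        if d.heavy_shift is None:
            skip["donor_without_heavy_shift"] += 1
            continue
        for a in groups:
            if d.label == a.label:
                continue
            dist = ensemble_pair_distance(ens, (d, a), tol, _cache=coord_cache)
            if isinstance(dist, np.ndarray):
                dist = _summarize(dist, "midrange")
            if dist > tol.distance_cutoff:
                skip["pairs_beyond_cutoff"] += 1
                continue
            noise = rng.normal(0.0, jitter, size=3) if jitter > 0 else np.zeros(3)
            rows.append(
                (
                    len(rows) + 1,
                    d.proton_shift + noise[0],
                    d.heavy_shift + noise[1],
                    a.proton_shift + noise[2],
                    np.nan,
                )
            )
    df = pd.DataFrame(
        rows, columns=["peak_id", "w_hdonor", "w_x", "w_hacceptor", "intensity"]
    )
    if df.empty:
        raise NoesyError("no proton pair within the cutoff; nothing to simulate")
    return PeakList(spectrum_type=spectrum_type, peaks=df), skip
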