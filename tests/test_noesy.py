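"""NOESY matching, recall, Double Recall, and peak simulation.

The brute-force oracle re-derives explained-peak sets by naive loops over
(peak, proton pair, model) triples, independently of the package's
matching machinery.
"""

import numpy as np
import pandas as pd
import pytest

from nmrselect.model_io import ConformerEnsemble, ConformerModel, PeakList, ShiftTable
from nmrselect.noesy import (
    MatchTolerances,
    NoesyError,
    double_recall,
    ensemble_pair_distance,
    build_proton_groups,
    match_peaks,
    score_recall,
    score_recall_per_model,
    simulate_peaks,
)


def _model(model_id, atom_rows, ptm=0.9):
    atoms = pd.DataFrame(
        atom_rows, columns=["chain", "resnum", "resname", "atom", "element", "x", "y", "z"]
    )
    resnums = sorted(set(atoms["resnum"]))
    plddt = pd.Series(80.0, index=pd.MultiIndex.from_tuples([("A", r) for r in resnums]))
    return ConformerModel(model_id, atoms, plddt, ptm)


def _shifts(rows):
    return ShiftTable(
        pd.DataFrame(rows, columns=["chain", "resnum", "restype", "atom", "shift"])
    )


def _peaks(rows, spectrum="N15-NOESY"):
    df = pd.DataFrame(
        [(i + 1, *r, np.nan) for i, r in enumerate(rows)],
        columns=["peak_id", "w_hdonor", "w_x", "w_hacceptor", "intensity"],
    )
    return PeakList(spectrum, df)


# two amide donors + two HA acceptors; CA atoms so models are valid
def _two_residue_system(d_h7_ha3=3.0):
    shifts = _shifts(
        [
            ("A", 3, "ALA", "H", 8.80), ("A", 3, "ALA", "N", 118.0),
            ("A", 3, "ALA", "HA", 4.10), ("A", 3, "ALA", "CA", 52.5),
            ("A", 7, "LEU", "H", 8.20), ("A", 7, "LEU", "N", 122.0),
            ("A", 7, "LEU", "HA", 4.50), ("A", 7, "LEU", "CA", 55.1),
        ]
    )
    rows = [
        ("A", 3, "ALA", "CA", "C", 0.0, 0.0, 0.0),
        ("A", 3, "ALA", "H", "H", 0.0, 1.0, 0.0),
        ("A", 3, "ALA", "HA", "H", 0.5, 0.0, 0.0),
        ("A", 7, "LEU", "CA", "C", 10.0, 0.0, 0.0),
        ("A", 7, "LEU", "H", "H", 0.5 + d_h7_ha3, 0.0, 0.0),
        ("A", 7, "LEU", "HA", "H", 10.5, 0.0, 0.0),
    ]
    return shifts, _model(1, rows)


class TestMatchPeaks:
    def test_exact_coincidence_found(self):
        shifts, _ = _two_residue_system()
        peaks = _peaks([(8.20, 122.0, 4.10)])
        cands = match_peaks(peaks, shifts, MatchTolerances())[0]
        labels = {(d.label, a.label) for d, a in cands}
        assert ("A:7:H", "A:3:HA") in labels

    def test_far_peak_unmatched(self):
        shifts, _ = _two_residue_system()
        cands = match_peaks(_peaks([(18.0, 140.0, 12.0)]), shifts, MatchTolerances())[0]
        assert cands == []

    def test_degenerate_donors_both_returned(self):
        shifts = _shifts(
            [
                ("A", 4, "ALA", "H", 8.20), ("A", 4, "ALA", "N", 120.0),
                ("A", 5, "SER", "H", 8.20), ("A", 5, "SER", "N", 120.0),
                ("A", 9, "GLY", "HA2", 3.90),
            ]
        )
        cands = match_peaks(_peaks([(8.20, 120.0, 3.90)]), shifts, MatchTolerances())[0]
        donors = {d.label for d, _ in cands}
        # exhaustive enumeration: both residues satisfy the donor windows
        expected = {
            f"A:{r}:H"
            for r in (4, 5)
            if abs(8.20 - 8.20) <= 0.05 and abs(120.0 - 120.0) <= 0.5
        }
        assert donors == expected == {"A:4:H", "A:5:H"}

    def test_diagonal_pairs_excluded(self):
        shifts, _ = _two_residue_system()
        # acceptor window centered on the donor's own shift
        cands = match_peaks(_peaks([(8.20, 122.0, 8.20)]), shifts, MatchTolerances())[0]
        assert all(d.label != a.label for d, a in cands)


class TestPairDistances:
    def _pair(self, shifts):
        groups = {g.label: g for g in build_proton_groups(shifts)}
        return groups["A:7:H"], groups["A:3:HA"]

    def test_single_model_euclidean(self):
        shifts, model = _two_residue_system(d_h7_ha3=3.0)
        pair = self._pair(shifts)
        ens = ConformerEnsemble("e", [model])
        assert ensemble_pair_distance(ens, pair, MatchTolerances()) == pytest.approx(3.0)

    def test_midrange_over_models(self):
        shifts, m1 = _two_residue_system(d_h7_ha3=3.0)
        _, m2 = _two_residue_system(d_h7_ha3=7.0)
        m2 = ConformerModel(2, m2.atoms, m2.plddt, m2.ptm)
        ens = ConformerEnsemble("e", [m1, m2])
        tol = MatchTolerances(ensemble_summarizer="midrange")
        assert ensemble_pair_distance(ens, self._pair(shifts), tol) == pytest.approx(5.0)
        tol_min = MatchTolerances(ensemble_summarizer="min")
        assert ensemble_pair_distance(ens, self._pair(shifts), tol_min) == pytest.approx(3.0)

    def test_merged_states_take_minimum_of_summaries(self):
        shifts, m1 = _two_residue_system(d_h7_ha3=5.4)
        _, m2 = _two_residue_system(d_h7_ha3=4.2)
        e1 = ConformerEnsemble("s1", [m1])
        e2 = ConformerEnsemble("s2", [ConformerModel(2, m2.atoms, m2.plddt, m2.ptm)])
        d = ensemble_pair_distance([e1, e2], self._pair(shifts), MatchTolerances())
        assert d == pytest.approx(4.2)

    def test_pseudo_atom_fallback_with_correction(self):
        shifts, model = _two_residue_system()
        # strip all protons: groups fall back to bonded heavy atoms
        atoms = model.atoms[model.atoms["element"] != "H"].reset_index(drop=True)
        rows = atoms.values.tolist()
        rows += [["A", 3, "ALA", "N", "N", 0.0, 0.0, 0.0],
                 ["A", 7, "LEU", "N", "N", 6.0, 0.0, 0.0]]
        bare = _model(1, rows)
        groups = {g.label: g for g in build_proton_groups(shifts)}
        pair = (groups["A:7:H"], groups["A:3:H"])
        ens = ConformerEnsemble("e", [bare])
        with pytest.warns(UserWarning, match="pseudo-atom"):
            d = ensemble_pair_distance(ens, pair, MatchTolerances())
        assert d == pytest.approx(6.0 - 2.0)  # 1 Å correction per side

    def test_tolerance_validation(self):
        with pytest.raises(NoesyError):
            MatchTolerances(h_ppm=-0.1)
        with pytest.raises(NoesyError):
            MatchTolerances(distance_cutoff=7.0)


class TestScoreRecall:
    def test_toy_counts(self):
        # 4 peaks: three match pairs within 5 Å, one matches a 9.5 Å pair
        shifts, model = _two_residue_system(d_h7_ha3=3.0)
        ens = ConformerEnsemble("e", [model])
        peaks = _peaks(
            [
                (8.20, 122.0, 4.10),   # H7-HA3: 3.0 Å -> explained
                (8.80, 118.0, 4.10),   # H3-HA3: ~1.1 Å -> explained
                (8.80, 118.0, 4.50),   # H3-HA7: ~10.5 Å -> unexplained
                (8.20, 122.0, 4.50),   # H7-HA7: 7 Å -> unexplained? see below
            ]
        )
        rep = score_recall(peaks, shifts, ens, MatchTolerances())
        statuses = list(rep.peak_table["status"])
        assert statuses[0] == "explained" and statuses[1] == "explained"
        assert rep.recall == pytest.approx(
            statuses.count("explained") / 4
        )
        assert 0.0 <= rep.precision <= 1.0
        assert 0.0 <= rep.f_measure <= 1.0

    def test_round_trip_recall_is_one(self, small_fixture, small_nmr):
        states = [small_fixture.state1, small_fixture.state2]
        rep = score_recall(
            list(small_nmr.peaks.values()), small_nmr.shifts, states, MatchTolerances()
        )
        assert rep.recall == 1.0

    def test_merged_recall_dominates_singles(self, small_fixture, small_nmr):
        peaks = list(small_nmr.peaks.values())
        tol = MatchTolerances()
        r_merged = score_recall(
            peaks, small_nmr.shifts, [small_fixture.state1, small_fixture.state2], tol
        ).recall
        r1 = score_recall(peaks, small_nmr.shifts, small_fixture.state1, tol).recall
        r2 = score_recall(peaks, small_nmr.shifts, small_fixture.state2, tol).recall
        assert r_merged >= max(r1, r2)

    def test_widening_tolerance_never_decreases_recall(self, small_fixture, small_nmr):
        jittered, _ = simulate_peaks(
            [small_fixture.state1, small_fixture.state2], small_nmr.shifts,
            MatchTolerances(), jitter=0.03, seed=5,
        )
        tight = score_recall(jittered, small_nmr.shifts, small_fixture.state1,
                             MatchTolerances(h_ppm=0.02)).recall
        wide = score_recall(jittered, small_nmr.shifts, small_fixture.state1,
                            MatchTolerances(h_ppm=0.08)).recall
        assert wide >= tight

    def test_empty_peak_list_rejected(self, small_nmr, small_fixture):
        empty = PeakList("N15-NOESY", pd.DataFrame(
            columns=["peak_id", "w_hdonor", "w_x", "w_hacceptor", "intensity"]))
        with pytest.raises(NoesyError, match="empty"):
            score_recall(empty, small_nmr.shifts, small_fixture.state1)

    def test_per_model_reports_carry_min_max(self, small_fixture, small_nmr):
        reports = score_recall_per_model(
            small_nmr.peaks["N15-NOESY"], small_nmr.shifts, small_fixture.state1
        )
        recalls = [r.recall for r in reports]
        assert reports[0].recall_min == min(recalls)
        assert reports[0].recall_max == max(recalls)


def oracle_explained_sets(peak_lists, shifts, states, tol):
    """Brute-force (peak x pair x model) enumeration of explained peaks."""
    entries = shifts.entries
    protons = entries[entries["atom"].str.startswith("H")]

    def group_of(row):
        a = row.atom
        if a in ("H", "HN"):
            return (row.chain, row.resnum, "H")
        return (row.chain, row.resnum, a[:-1] if a[-1:].isdigit() else a)

    def heavy_of(row):
        if row.atom in ("H", "HN"):
            return "N"
        base = row.atom[1:]
        for cand in ["C" + base] + (["C" + base[:-1]] if base[-1:].isdigit() else []):
            if shifts.get(row.chain, row.resnum, cand) is not None:
                return cand
        return "C" + base

    def atom_expansion(model, row):
        out = []
        if model.has_atom(row.chain, row.resnum, row.atom):
            out.append(row.atom)
        for i in (1, 2, 3):
            if model.has_atom(row.chain, row.resnum, f"{row.atom}{i}"):
                out.append(f"{row.atom}{i}")
        return out

    def pair_dist(h1, h2):
        summaries = []
        for state in states:
            per_model = []
            for m in state.models:
                best = np.inf
                for a1 in atom_expansion(m, h1):
                    for a2 in atom_expansion(m, h2):
                        d = np.linalg.norm(
                            m.coord(h1.chain, h1.resnum, a1)
                            - m.coord(h2.chain, h2.resnum, a2)
                        )
                        best = min(best, d)
                per_model.append(best)
            summaries.append((min(per_model) + max(per_model)) / 2.0)
        return min(summaries)

    explained = set()
    for plist in peak_lists:
        heavy_el = "N" if plist.spectrum_type == "N15-NOESY" else "C"
        tol_x = tol.n_ppm if heavy_el == "N" else tol.c_ppm
        for peak in plist.peaks.itertuples(index=False):
            hit = False
            for h1 in protons.itertuples(index=False):
                if hit:
                    break
                heavy = heavy_of(h1)
                if heavy[0] != heavy_el:
                    continue
                hshift = shifts.get(h1.chain, h1.resnum, heavy)
                if hshift is None:
                    continue
                if abs(h1.shift - peak.w_hdonor) > tol.h_ppm:
                    continue
                if abs(hshift - peak.w_x) > tol_x:
                    continue
                for h2 in protons.itertuples(index=False):
                    if group_of(h1) == group_of(h2):
                        continue
                    if abs(h2.shift - peak.w_hacceptor) > tol.h_ppm:
                        continue
                    if pair_dist(h1, h2) <= tol.distance_cutoff:
                        explained.add((plist.spectrum_type, peak.peak_id))
                        hit = True
                        break
    return explained


class TestOracleEquivalence:
    def test_explained_sets_match_bruteforce(self, small_fixture, small_nmr):
        tol = MatchTolerances()
        states = [small_fixture.state1, small_fixture.state2]
        peaks = list(small_nmr.peaks.values())
        rep = score_recall(peaks, small_nmr.shifts, states, tol)
        oracle = oracle_explained_sets(peaks, small_nmr.shifts, states, tol)
        assert rep.explained_keys() == oracle


class TestDoubleRecall:
    def test_identical_ensembles_no_uniques(self, small_fixture, small_nmr):
        peaks = small_nmr.peaks["N15-NOESY"]
        rep = score_recall(peaks, small_nmr.shifts, small_fixture.state1)
        result = double_recall(rep, rep)
        assert result.unique_to_a == set() and result.unique_to_b == set()
        assert result.shared == rep.explained_keys()

    def test_constructed_unique_peak(self):
        shifts, m_close = _two_residue_system(d_h7_ha3=4.0)
        _, m_far = _two_residue_system(d_h7_ha3=8.0)
        m_far = ConformerModel(2, m_far.atoms, m_far.plddt, m_far.ptm)
        peaks = _peaks([(8.20, 122.0, 4.10)])
        rep_a = score_recall(peaks, shifts, ConformerEnsemble("A", [m_close]))
        rep_b = score_recall(peaks, shifts, ConformerEnsemble("B", [m_far]))
        result = double_recall(rep_a, rep_b)
        assert result.unique_to_a == {("N15-NOESY", 1)}
        assert result.unique_to_b == set()

    def test_partition_is_disjoint_and_exhaustive(self, small_fixture, small_nmr):
        peaks = list(small_nmr.peaks.values())
        rep_a = score_recall(peaks, small_nmr.shifts, small_fixture.state1)
        rep_b = score_recall(peaks, small_nmr.shifts, small_fixture.state2)
        res = double_recall(rep_a, rep_b)
        assert res.unique_to_a.isdisjoint(res.unique_to_b)
        assert res.unique_to_a.isdisjoint(res.shared)
        assert res.unique_to_b.isdisjoint(res.shared)
        assert (res.unique_to_a | res.unique_to_b | res.shared) == (
            rep_a.explained_keys() | rep_b.explained_keys()
        )
        assert res.unique_to_a | res.shared == rep_a.explained_keys()

    def test_mismatched_universes_rejected(self, small_fixture, small_nmr):
        p1 = small_nmr.peaks["N15-NOESY"]
        sub = PeakList("N15-NOESY", p1.peaks.iloc[:-1].copy())
        rep_a = score_recall(p1, small_nmr.shifts, small_fixture.state1)
        rep_b = score_recall(sub, small_nmr.shifts, small_fixture.state1)
        with pytest.raises(NoesyError, match="identical peak lists"):
            double_recall(rep_a, rep_b)

    def test_contact_map_collapses_residue_pairs(self, small_fixture, small_nmr):
        peaks = list(small_nmr.peaks.values())
        rep_a = score_recall(peaks, small_nmr.shifts, small_fixture.state1)
        rep_b = score_recall(peaks, small_nmr.shifts, small_fixture.state2)
        res = double_recall(rep_a, rep_b)
        shared = res.contacts[res.contacts["set"] == "shared"]
        assert not shared.duplicated(subset=["res_i", "res_j"]).any()
        assert int(shared["count"].sum()) == len(res.shared)


class TestSimulatePeaks:
    def test_close_pair_yields_one_peak_at_shifts(self):
        shifts, model = _two_residue_system(d_h7_ha3=3.0)
        # restrict shifts to one donor (H7) and one acceptor (HA3)
        keep = shifts.entries[
            shifts.entries.apply(
                lambda r: (r.resnum, r.atom) in [(7, "H"), (7, "N"), (3, "HA")], axis=1
            )
        ]
        small = ShiftTable(keep.reset_index(drop=True))
        plist, skip = simulate_peaks(
            ConformerEnsemble("e", [model]), small, MatchTolerances(), jitter=0.0
        )
        assert len(plist) == 1
        row = plist.peaks.iloc[0]
        assert row.w_hdonor == pytest.approx(8.20)
        assert row.w_x == pytest.approx(122.0)
        assert row.w_hacceptor == pytest.approx(4.10)

    def test_far_pair_produces_no_peak(self):
        shifts, model = _two_residue_system(d_h7_ha3=8.0)
        keep = shifts.entries[
            shifts.entries.apply(
                lambda r: (r.resnum, r.atom) in [(7, "H"), (7, "N"), (3, "HA")], axis=1
            )
        ]
        small = ShiftTable(keep.reset_index(drop=True))
        with pytest.raises(NoesyError, match="nothing to simulate"):
            simulate_peaks(ConformerEnsemble("e", [model]), small, MatchTolerances())

    def test_seeded_jitter_deterministic(self, small_fixture, small_nmr):
        args = ([small_fixture.state1], small_nmr.shifts, MatchTolerances())
        p1, _ = simulate_peaks(*args, jitter=0.02, seed=42)
        p2, _ = simulate_peaks(*args, jitter=0.02, seed=42)
        pd.testing.assert_frame_equal(p1.peaks, p2.peaks)
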