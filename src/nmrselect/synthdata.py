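"""Seeded generator of two-state toy ensembles with matched synthetic
chemical shifts and NOESY peaks.

The fixture is a helix-loop-helix peptide built in torsion space from
ideal peptide geometry (backbone N/CA/C/O, CB, amide H, HA, and a methyl
on every alanine).  State 2 differs from state 1 by a hinge: the ψ torsion
of the hinge residue is offset by the hinge angle, swinging the C-terminal
helix.  Each model draws a small per-model hinge-angle jitter — mimicking
the continuous spread of enhanced-sampling models, and giving single-state
ensembles an RMSF profile that correlates with true flexibility — plus
isotropic Gaussian coordinate noise.

The matched NMR data are internally consistent rather than physically
realistic: secondary shifts are sized so the RCI pipeline approximately
recovers the planted pooled RMSF, and NOESY peaks are back-calculated from
the merged true states.  pLDDT is assigned anti-monotone to true RMSF and
pTM per state, so every term of the Bayesian selection score is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import ConformerEnsemble, ConformerModel, PeakList, ShiftTable, merge_ensembles
from .noesy import MatchTolerances, simulate_peaks
from .shifts import (
    RCI_CEILING,
    RCI_TO_RMSF,
    default_random_coil_table,
    default_rci_weights,
)

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# repeating alanine-rich pattern (no Gly/Pro) used for default sequences
_SEQ_PATTERN = "AEKLADSVATMRANQY"

HELIX_PHI, HELIX_PSI = -57.0, -47.0
# turn torsions folding the chain into a packed helix hairpin; the hinge
# (the last turn residue's psi) opens the packing when rotated positive
TURN_TORSIONS = ((70.0, -60.0), (-120.0, 60.0), (-140.0, 150.0))


class SynthError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Study conditions for the planted two-state fixture."""

    n_residues: int = 30
    hinge_residue: int | None = None  # psi of this residue carries the hinge; default midpoint
    hinge_angle_deg: float = 25.0
    n_models_per_state: int = 20
    noise_sigma: float = 0.3         # Å, isotropic per atom coordinate
    angle_jitter_deg: float = 3.0    # per-model hinge-angle spread
    plddt_range: tuple[float, float] = (55.0, 95.0)
    ptm_by_state: tuple[float, float] = (0.90, 0.85)
    shift_dialect: str = "tsv"
    peak_jitter_ppm: float = 0.0
    seed: int = 0
    sequence: str | None = None      # 1-letter; default pattern if None

    def __post_init__(self) -> None:
        if min(self.n_residues, self.n_models_per_state) < 1:
            raise SynthError("counts must be positive")
        if self.hinge_residue is None:
            self.hinge_residue = self.n_residues // 2
        if not 3 < self.hinge_residue < self.n_residues - 1:
            raise SynthError("hinge residue must leave room for the turn and tail")
        if self.noise_sigma < 0 or self.peak_jitter_ppm < 0:
            raise SynthError("noise levels must be non-negative")

    def resolved_sequence(self) -> str:
        if self.sequence:
            if len(self.sequence) != self.n_residues:
                raise SynthError("sequence length must equal n_residues")
            return self.sequence.upper()
        reps = -(-self.n_residues // len(_SEQ_PATTERN))
        return (_SEQ_PATTERN * reps)[: self.n_residues]


# ---------------------------------------------------------------------------
# Torsion-space peptide builder
# ---------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d after a-b-c."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * math.cos(ang),
         bond * math.cos(tor) * math.sin(ang),
         bond * math.sin(tor) * math.sin(ang)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_torsions(n_res: int, hinge: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed helix-turn-helix φ/ψ profile.

    The three turn residues end at the hinge residue (1-based), whose ψ
    carries the hinge rotation: ψ + 0° is the closed (packed) state and
    positive offsets progressively open the hairpin, losing long-range
    contacts.
    """
    phi = np.full(n_res, HELIX_PHI)
    psi = np.full(n_res, HELIX_PSI)
    for k, (p, q) in enumerate(TURN_TORSIONS):
        i = hinge - 3 + k  # 0-based residues hinge-2 .. hinge
        if 0 <= i < n_res:
            phi[i], psi[i] = p, q
    return phi, psi


def build_peptide(
    sequence: str,
    phi: Sequence[float],
    psi: Sequence[float],
    chain: str = "A",
) -> pd.DataFrame:
    """Build an all-residue peptide (N, CA, C, O, CB, H, HA, Ala methyls)
    from ideal internal coordinates.  Returns an atom DataFrame."""
    n_res = len(sequence)
    rows = []

    def add(resnum, resname, atom, element, pos):
        rows.append((chain, resnum, resname, atom, element, *pos))

    # seed residue 1 backbone in a canonical frame
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array(
        [math.cos(math.radians(180 - 111.2)), math.sin(math.radians(180 - 111.2)), 0.0]
    )
    # virtual previous carbonyl so phi(1) is defined
    cprev = _place(c, ca, n, 1.329, 121.7, phi[0])
    prev = {"CA": None, "C": None}
    for i in range(n_res):
        resnum = i + 1
        resname = AA1TO3[sequence[i]]
        if i > 0:
            n = _place(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi[i - 1])
            ca = _place(prev["CA"], prev["C"], n, 1.458, 121.7, 180.0)  # omega trans
            c = _place(prev["C"], n, ca, 1.525, 111.2, phi[i])
            cprev = prev["C"]
        add(resnum, resname, "N", "N", n)
        add(resnum, resname, "CA", "C", ca)
        add(resnum, resname, "C", "C", c)
        if i < n_res - 1:
            o = _place(n, ca, c, 1.231, 120.8, psi[i] + 180.0)
        else:
            o = _place(n, ca, c, 1.231, 120.8, psi[i])
        add(resnum, resname, "O", "O", o)
        if resname != "PRO":
            # amide proton trans to CA across the C(i-1)-N bond
            add(resnum, resname, "H", "H", _place(ca, cprev, n, 1.01, 119.0, 180.0))
        if resname != "GLY":
            # L configuration: CB sits at phi - 122.5 about the N-CA axis
            cb = _place(cprev, n, ca, 1.521, 110.4, phi[i] - 122.5)
            add(resnum, resname, "CB", "C", cb)
            ha = _place(cprev, n, ca, 1.09, 108.9, phi[i] + 119.3)
            add(resnum, resname, "HA", "H", ha)
            if resname == "ALA":
                for j, tor in enumerate((60.0, 180.0, 300.0), start=1):
                    hb = _place(n, ca, cb, 1.09, 109.5, tor)
                    add(resnum, resname, f"HB{j}", "H", hb)
        else:
            ha = _place(cprev, n, ca, 1.09, 108.9, phi[i] + 119.3)
            add(resnum, resname, "HA2", "H", ha)
            ha3 = _place(cprev, n, ca, 1.09, 108.9, phi[i] - 122.5)
            add(resnum, resname, "HA3", "H", ha3)
        prev = {"N": n, "CA": ca, "C": c}

    return pd.DataFrame(
        rows, columns=["chain", "resnum", "resname", "atom", "element", "x", "y", "z"]
    )


# ---------------------------------------------------------------------------
# Two-state fixture
# ---------------------------------------------------------------------------

def _add_residue_noise(df: pd.DataFrame, sigma: float, rng: np.random.Generator) -> pd.DataFrame:
    """Per-residue rigid Gaussian displacement (σ per coordinate).

    Noise is applied per residue, not per atom, so local covalent geometry
    and stereochemistry stay intact — as in real sampling ensembles, whose
    deviations are smooth rather than atomically independent.
    """
    atoms = df.copy()
    if sigma > 0:
        for resnum, idx in atoms.groupby("resnum").groups.items():
            atoms.loc[idx, ["x", "y", "z"]] += rng.normal(0.0, sigma, size=3)
    return atoms


@dataclass
class TwoStateFixture:
    """Planted two-state ensemble with ground truth."""

    state1: ConformerEnsemble
    state2: ConformerEnsemble
    pooled: ConformerEnsemble
    true_labels: list[int]           # state index per pooled model
    true_rmsf: pd.Series             # per-residue pooled Cα RMSF, Å
    mean_structures: tuple[pd.DataFrame, pd.DataFrame]
    spec: FixtureSpec = field(repr=False, default=None)


def _model_from_atoms(
    model_id: int, atoms: pd.DataFrame, plddt: pd.Series, ptm: float
) -> ConformerModel:
    return ConformerModel(model_id=model_id, atoms=atoms, plddt=plddt, ptm=ptm)


def make_two_state_ensemble(spec: FixtureSpec | None = None) -> TwoStateFixture:
    """Generate the planted two-state conformer ensembles.

    State 2 equals state 1 with the hinge residue's ψ offset by the hinge
    angle; each model adds per-model hinge jitter and isotropic coordinate
    noise.  The true pooled RMSF is the exact construction value: the RMS
    deviation of the noiseless per-model Cα positions about their pooled
    mean plus the isotropic noise term, √(⟨|Δ|²⟩ + 3σ²).
    """
    spec = spec or FixtureSpec()
    if spec.hinge_angle_deg == 0:
        import warnings

        warnings.warn("hinge angle 0: the two states are identical")
    rng = np.random.default_rng(spec.seed)
    seq = spec.resolved_sequence()
    phi, psi = _backbone_torsions(spec.n_residues, spec.hinge_residue)
    h = spec.hinge_residue - 1  # 0-based

    # per-model hinge angles: state offsets plus jitter
    offsets = [0.0, spec.hinge_angle_deg]
    noiseless: list[tuple[int, pd.DataFrame]] = []
    for state, offset in enumerate(offsets):
        for _ in range(spec.n_models_per_state):
            dpsi = offset + rng.normal(0.0, spec.angle_jitter_deg)
            psi_m = psi.copy()
            psi_m[h] += dpsi
            noiseless.append((state, build_peptide(seq, phi, psi_m)))

    # exact construction RMSF about the pooled mean (Cα only)
    ca_stack = np.stack(
        [df.loc[df.atom == "CA", ["x", "y", "z"]].to_numpy(float) for _, df in noiseless]
    )
    dev = ca_stack - ca_stack.mean(axis=0)
    construction = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    true_rmsf_vals = np.sqrt(construction**2 + 3.0 * spec.noise_sigma**2)
    resnums = [int(r) for r in noiseless[0][1].loc[noiseless[0][1].atom == "CA", "resnum"]]
    index = pd.MultiIndex.from_tuples([("A", r) for r in resnums])
    true_rmsf = pd.Series(true_rmsf_vals, index=index)

    # pLDDT: monotone-decreasing map of true RMSF onto plddt_range
    lo, hi = spec.plddt_range
    rmin, rmax = float(true_rmsf.min()), float(true_rmsf.max())
    span = (rmax - rmin) or 1.0
    plddt = hi - (hi - lo) * (true_rmsf - rmin) / span
    plddt.name = "plddt"

    state_models: list[list[ConformerModel]] = [[], []]
    labels = []
    for k, (state, df) in enumerate(noiseless):
        atoms = _add_residue_noise(df, spec.noise_sigma, rng)
        m = _model_from_atoms(k + 1, atoms, plddt, spec.ptm_by_state[state])
        state_models[state].append(m)
        labels.append(state)

    state1 = ConformerEnsemble("state1", state_models[0])
    state2 = ConformerEnsemble("state2", state_models[1])
    pooled = merge_ensembles("pooled", [state1, state2])

    mean1 = build_peptide(seq, phi, psi)
    psi2 = psi.copy()
    psi2[h] += spec.hinge_angle_deg
    mean2 = build_peptide(seq, phi, psi2)
    return TwoStateFixture(
        state1=state1, state2=state2, pooled=pooled, true_labels=labels,
        true_rmsf=true_rmsf, mean_structures=(mean1, mean2), spec=spec,
    )


def make_decoy_ensemble(spec: FixtureSpec, n_models: int | None = None) -> ConformerEnsemble:
    """A decoy state hinged far past both planted states (ψ offset 3×).

    Over-opening the hairpin destroys the packing contacts that generated
    the NOESY data, so the decoy's own contacts are absent from the peak
    list and its recall falls below either true state.  (A decoy hinged in
    the closing direction would only gain contacts — recall cannot punish
    spurious compactness; that is what precision measures.)
    """
    n = n_models or spec.n_models_per_state
    rng = np.random.default_rng(spec.seed + 104729)
    seq = spec.resolved_sequence()
    phi, psi = _backbone_torsions(spec.n_residues, spec.hinge_residue)
    h = spec.hinge_residue - 1
    fx = make_two_state_ensemble(spec)
    plddt = fx.state1.models[0].plddt
    models = []
    for k in range(n):
        psi_m = psi.copy()
        psi_m[h] += 3.0 * spec.hinge_angle_deg + rng.normal(0.0, spec.angle_jitter_deg)
        atoms = _add_residue_noise(build_peptide(seq, phi, psi_m), spec.noise_sigma, rng)
        models.append(_model_from_atoms(k + 1, atoms, plddt, min(spec.ptm_by_state)))
    return ConformerEnsemble("decoy", models)


# ---------------------------------------------------------------------------
# Matched synthetic NMR data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNmr:
    """Matched shift table and back-calculated peak lists for a fixture."""

    shifts: ShiftTable
    peaks: dict[str, PeakList]       # spectrum type -> peaks
    target_rci: pd.Series            # planted per-residue RCI
    skip_reports: dict[str, dict]


# relative secondary-shift scale per resonance; protons kept small (ppm-
# realistic) and heavy atoms absorb the remainder of the weighted mean
_PROTON_SCALE = 0.03


def _secondary_shift_scales(weights: dict[str, float]) -> dict[str, float]:
    heavy = [k for k in weights if k not in ("H", "HA")]
    protons = [k for k in weights if k in ("H", "HA")]
    wsum = sum(weights.values())
    wp = sum(weights[k] * _PROTON_SCALE for k in protons)
    x = (wsum - wp) / sum(weights[k] for k in heavy)
    scales = {k: x for k in heavy}
    scales.update({k: _PROTON_SCALE for k in protons})
    return scales


def make_synthetic_nmr(
    fixture: TwoStateFixture,
    tol: MatchTolerances | None = None,
    rci_floor: float = 0.02,
) -> SyntheticNmr:
    """Assign shifts consistent with the planted RMSF and back-calculate peaks.

    Secondary shifts are sized so that the RCI pipeline (reciprocal of the
    weighted mean |Δδ|, cap, three-point smoothing, ×12.7 Å) approximately
    recovers the fixture's true pooled RMSF.  NOESY peaks (¹⁵N and ¹³C
    spectra) are simulated from the merged true states under the
    minimum-distance rule.
    """
    spec = fixture.spec
    tol = tol or MatchTolerances()
    rng = np.random.default_rng(spec.seed + 7919)
    rc = default_random_coil_table()
    rc_map = {
        (row.restype, row.atom): row.shift
        for row in rc.entries.itertuples(index=False)
    }
    weights = default_rci_weights()
    scales = _secondary_shift_scales(weights)

    rmsf = fixture.true_rmsf
    if (rmsf <= 0).any() or (rmsf > RCI_CEILING * RCI_TO_RMSF + 1e-9).any():
        raise SynthError(
            "true RMSF outside the RCI-representable range (0, 7.62] Å"
        )
    target = (rmsf / RCI_TO_RMSF).clip(lower=rci_floor, upper=RCI_CEILING)

    residues = fixture.pooled.residues()
    rows = []
    for chain, resnum, resname in residues:
        m = 1.0 / float(target[(chain, resnum)])  # required weighted-mean |Δδ|
        for res_type in ("CA", "C", "CB", "N", "H", "HA"):
            ref = rc_map.get((resname, res_type))
            if ref is None:
                continue
            sign = rng.choice([-1.0, 1.0])
            rows.append((chain, resnum, resname, res_type, ref + sign * scales[res_type] * m))
        if resname == "ALA":  # single methyl assignment, expands to HB1-3
            rows.append((chain, resnum, resname, "HB", 1.39 + rng.normal(0.0, 0.15)))
    shifts = ShiftTable(
        pd.DataFrame(rows, columns=["chain", "resnum", "restype", "atom", "shift"])
    )

    peaks = {}
    skips = {}
    for spectrum in ("N15-NOESY", "C13-NOESY"):
        plist, skip = simulate_peaks(
            [fixture.state1, fixture.state2], shifts, tol,
            spectrum_type=spectrum, jitter=spec.peak_jitter_ppm,
            seed=spec.seed + (11 if spectrum.startswith("N") else 13),
        )
        peaks[spectrum] = plist
        skips[spectrum] = skip
    return SyntheticNmr(
        shifts=shifts, peaks=peaks, target_rci=target, skip_reports=skips
    )
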