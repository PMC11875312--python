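"""Random coil index (RCI) and shift-derived RMSF from chemical shifts.

The RCI of a residue is the reciprocal of the weighted mean of the absolute
secondary shifts |Δδ| = |δ_observed - δ_random_coil| over the six backbone
resonances Cα, CO, Cβ, N, NH, and Hα, with weights A-F renormalized over
the resonances actually available.  Values above 0.6 are capped at 0.6 and
the capped profile is smoothed with a three-point sliding mean along the
sequence (window shrunk at chain ends and sequence gaps).  RCI0.6 = RCI/0.6
rescales the result to (0, 1], and RMSF_RCI = RCI × 12.7 Å converts it to a
per-residue fluctuation estimate.

The weighting coefficients and the random-coil reference table ship as
package data and are fully configurable; exact parity with any particular
RCI server implementation is not promised.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RmsfProfile
from .model_io import ShiftTable

RCI_CEILING = 0.6
RCI_TO_RMSF = 12.7  # Å per RCI unit

#: The six RCI resonance types in weight order A-F (NH is the amide proton H).
RCI_RESONANCES = ("CA", "C", "CB", "N", "H", "HA")


class RciError(ValueError):
    pass


@dataclass
class RciProfile:
    """Per-residue RCI pipeline output.

    ``table`` columns: raw_rci, capped_rci, smoothed_rci (the final RCI),
    rci06, n_resonances; indexed by (chain, resnum).  Residues with no
    usable resonance are absent, not zero.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.table["smoothed_rci"]
        if len(s) and not ((s > 0).all() and (s <= RCI_CEILING + 1e-12).all()):
            raise RciError("smoothed RCI outside (0, 0.6]")

    @property
    def rci(self) -> pd.Series:
        return self.table["smoothed_rci"]

    @property
    def rci06(self) -> pd.Series:
        return self.table["rci06"]

    def residues(self) -> list[tuple[str, int]]:
        return list(self.table.index)


def default_rci_weights() -> dict[str, float]:
    """Packaged A-F weighting coefficients (Cα, CO, Cβ, N, NH, Hα)."""
    text = resources.files("nmrselect.data").joinpath("rci_weights.json").read_text()
    return {k: float(v) for k, v in json.loads(text).items()}


def default_random_coil_table() -> ShiftTable:
    """Packaged random-coil reference shifts (literature values).

    Entries use chain "*" meaning "any chain"; lookup is by residue type.
    """
    with resources.files("nmrselect.data").joinpath("random_coil_shifts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return ShiftTable(
        pd.DataFrame(
            {
                "chain": "*",
                # reference table is keyed by residue type, not position;
                # fake distinct resnums to satisfy the uniqueness invariant
                "resnum": pd.factorize(df["residue_type"])[0] + 1,
                "restype": df["residue_type"],
                "atom": df["atom_name"],
                "shift": df["shift_ppm"],
            }
        )
    )


def load_random_coil_table(path: str | Path) -> ShiftTable:
    """Load a user random-coil TSV (residue_type, atom_name, shift_ppm)."""
    df = pd.read_csv(path, sep="\t")
    need = ["residue_type", "atom_name", "shift_ppm"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise RciError(f"random-coil table missing columns {missing}")
    return ShiftTable(
        pd.DataFrame(
            {
                "chain": "*",
                "resnum": pd.factorize(df["residue_type"])[0] + 1,
                "restype": df["residue_type"],
                "atom": df["atom_name"],
                "shift": df["shift_ppm"],
            }
        )
    )


def _random_coil_lookup(table: ShiftTable) -> dict[tuple[str, str], float]:
    return {
        (row.restype, row.atom): row.shift
        for row in table.entries.itertuples(index=False)
    }


def _canonical_resonance(atom: str) -> str | None:
    """Map an observed atom name onto one of the six RCI resonance types."""
    atom = atom.upper()
    if atom in RCI_RESONANCES:
        return atom
    if atom in ("HN",):
        return "H"
    if atom in ("HA2", "HA3"):  # Gly methylene protons average onto HA
        return "HA"
    if atom in ("CO", "C'"):
        return "C"
    return None


def compute_rci(
    shifts: ShiftTable,
    coeffs: dict[str, float] | None = None,
    random_coil: ShiftTable | None = None,
) -> RciProfile:
    """Compute the per-residue RCI profile from observed chemical shifts.

    Per residue, raw RCI = 1 / (Σ w_X |Δδ_X| / Σ w_X) over the available
    resonances; a zero weighted mean maps to the 0.6 ceiling (rigid limit of
    the reciprocal is +∞, capped).  Capping precedes smoothing.
    """
    coeffs = dict(coeffs or default_rci_weights())
    unknown = set(coeffs) - set(RCI_RESONANCES)
    if unknown:
        raise RciError(f"unknown resonance types in coefficients: {sorted(unknown)}")
    if any(v <= 0 for v in coeffs.values()):
        raise RciError("RCI coefficients must be positive")
    rc = _random_coil_lookup(random_coil or default_random_coil_table())

    # gather |Δδ| per residue per resonance type (Gly HA2/HA3 averaged)
    acc: dict[tuple[str, int], dict[str, list[float]]] = {}
    skipped_types: set[str] = set()
    for row in shifts.entries.itertuples(index=False):
        res = _canonical_resonance(row.atom)
        if res is None or res not in coeffs:
            continue
        ref = rc.get((row.restype, res))
        if ref is None:
            if row.restype not in skipped_types:
                warnings.warn(
                    f"residue type {row.restype} absent from random-coil table; skipped"
                )
                skipped_types.add(row.restype)
            continue
        acc.setdefault((row.chain, int(row.resnum)), {}).setdefault(res, []).append(
            abs(row.shift - ref)
        )

    rows = []
    for (chain, resnum), per_res in sorted(acc.items()):
        num = den = 0.0
        for res, vals in per_res.items():
            num += coeffs[res] * float(np.mean(vals))
            den += coeffs[res]
        mean_dd = num / den
        raw = np.inf if mean_dd == 0 else 1.0 / mean_dd
        rows.append((chain, resnum, raw, min(raw, RCI_CEILING), len(per_res)))
    if not rows:
        raise RciError("no usable resonances in shift table")
    df = pd.DataFrame(
        rows, columns=["chain", "resnum", "raw_rci", "capped_rci", "n_resonances"]
    ).set_index(["chain", "resnum"])

    # three-point sliding mean, window shrunk at chain ends and gaps
    smoothed = {}
    for (chain, resnum), row in df.iterrows():
        window = [row["capped_rci"]]
        for nb in (resnum - 1, resnum + 1):
            if (chain, nb) in df.index:
                window.append(df.loc[(chain, nb), "capped_rci"])
        smoothed[(chain, resnum)] = float(np.mean(window))
    df["smoothed_rci"] = pd.Series(smoothed)
    df["rci06"] = df["smoothed_rci"] / RCI_CEILING
    return RciProfile(
        table=df[["raw_rci", "capped_rci", "smoothed_rci", "rci06", "n_resonances"]]
    )


def rmsf_from_rci(profile: RciProfile) -> RmsfProfile:
    """RMSF_RCI = RCI × 12.7 Å per residue (absent residues stay absent)."""
    return RmsfProfile(values=profile.rci * RCI_TO_RMSF, source="rci")
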