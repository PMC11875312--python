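"""Readers and writers for conformer ensembles, chemical shifts, and NOESY peak lists.

Conventions
-----------
* Multi-model PDB / mmCIF files carry per-residue pLDDT in the B-factor
  column (the AlphaFold convention); per-model pTM lives in a sidecar JSON
  file mapping ``model_id -> pTM`` because coordinate formats have no
  standard slot for it.
* Residue numbering is 1-based author numbering throughout; insertion
  codes are rejected.
* Chemical shifts come either from NMR-STAR 3.1 (the ``Atom_chem_shift``
  loop) or from a simple TSV dialect with columns
  ``chain  residue_number  residue_type  atom_name  shift_ppm``.
* NOESY peak lists are tab-separated ``w1 w2 w3 [intensity]`` with the
  dimension order (H-donor, heavy atom bonded to the donor, H-acceptor),
  in ppm.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("nmrselect")

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "element", "x", "y", "z"]


class ModelIOError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ConformerModel:
    """A single conformer: atoms, per-residue pLDDT, optional pTM.

    ``atoms`` is a DataFrame with columns ``chain, resnum, resname, atom,
    element, x, y, z`` (coordinates in Å).  ``plddt`` is indexed by
    ``(chain, resnum)`` on the 0-100 scale.
    """

    model_id: int
    atoms: pd.DataFrame
    plddt: pd.Series
    ptm: float | None = None
    _lookup: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ModelIOError(f"model {self.model_id}: non-finite coordinates")
        if len(self.plddt) and not (
            (self.plddt >= 0).all() and (self.plddt <= 100).all()
        ):
            raise ModelIOError(f"model {self.model_id}: pLDDT outside [0, 100]")
        dup = self.atoms.duplicated(subset=["chain", "resnum", "atom"])
        if dup.any():
            row = self.atoms[dup].iloc[0]
            raise ModelIOError(
                f"model {self.model_id}: duplicate atom {row.atom} in "
                f"residue {row.chain}:{row.resnum}"
            )
        for chain, resnum, resname in self.residues():
            if resname in STANDARD_AA:
                if not len(self._atom_rows(chain, resnum, "CA")):
                    raise ModelIOError(
                        f"model {self.model_id}: residue {chain}:{resnum} "
                        f"({resname}) has no CA atom"
                    )

    def residues(self) -> list[tuple[str, int, str]]:
        """Residues as ``(chain, resnum, resname)`` in file order."""
        seen: dict[tuple, str] = {}
        for chain, resnum, resname in zip(
            self.atoms["chain"], self.atoms["resnum"], self.atoms["resname"]
        ):
            seen.setdefault((chain, int(resnum)), resname)
        return [(c, r, n) for (c, r), n in seen.items()]

    def _index(self) -> dict:
        if self._lookup is None:
            self._lookup = {}
            for i, (c, r, a) in enumerate(
                zip(self.atoms["chain"], self.atoms["resnum"], self.atoms["atom"])
            ):
                self._lookup[(c, int(r), a)] = i
        return self._lookup

    @property
    def xyz(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (cached)."""
        if not hasattr(self, "_xyz") or self._xyz is None:
            self._xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        return self._xyz

    def _atom_rows(self, chain: str, resnum: int, atom: str) -> list[int]:
        i = self._index().get((chain, int(resnum), atom))
        return [] if i is None else [i]

    def has_atom(self, chain: str, resnum: int, atom: str) -> bool:
        return (chain, int(resnum), atom) in self._index()

    def coord(self, chain: str, resnum: int, atom: str) -> np.ndarray:
        """Coordinates of one atom; KeyError if absent."""
        i = self._index().get((chain, int(resnum), atom))
        if i is None:
            raise KeyError(f"atom {atom} of residue {chain}:{resnum} not in model")
        return self.xyz[i]

    def ca_coords(self, residues: Sequence[tuple[str, int]] | None = None) -> np.ndarray:
        """(n, 3) array of Cα coordinates for ``residues`` (default: all)."""
        if residues is None:
            residues = [(c, r) for c, r, _ in self.residues()]
        return np.array([self.coord(c, r, "CA") for c, r in residues], float)


@dataclass
class ConformerEnsemble:
    """An ordered collection of same-sequence conformer models."""

    label: str
    models: list[ConformerModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ModelIOError(f"ensemble {self.label!r} is empty")
        ref = self.models[0].residues()
        for m in self.models[1:]:
            got = m.residues()
            if got != ref:
                bad = _first_sequence_mismatch(ref, got)
                raise ModelIOError(
                    f"ensemble {self.label!r}: model {m.model_id} sequence "
                    f"mismatch at residue {bad}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def residues(self) -> list[tuple[str, int, str]]:
        return self.models[0].residues()

    def residue_keys(self) -> list[tuple[str, int]]:
        return [(c, r) for c, r, _ in self.residues()]

    def plddt_avg(self) -> pd.Series:
        """Per-residue pLDDT averaged over models (0-100 scale)."""
        return pd.concat([m.plddt for m in self.models], axis=1).mean(axis=1)

    def subset(self, model_ids: Iterable[int], label: str | None = None) -> "ConformerEnsemble":
        wanted = list(model_ids)
        by_id = {m.model_id: m for m in self.models}
        return ConformerEnsemble(label or self.label, [by_id[i] for i in wanted])


def _first_sequence_mismatch(ref, got):
    ref_set, got_set = set(ref), set(got)
    only_ref = [t for t in ref if t not in got_set]
    only_got = [t for t in got if t not in ref_set]
    if only_ref or only_got:
        t = (only_ref or only_got)[0]
        return f"{t[0]}:{t[1]} ({t[2]}, present in only one model)"
    for a, b in zip(ref, got):
        if a != b:
            return f"{b[0]}:{b[1]} ({b[2]} vs expected {a[2]})"
    return "unknown"


def merge_ensembles(label: str, ensembles: Sequence[ConformerEnsemble]) -> ConformerEnsemble:
    """Pool the models of several same-sequence ensembles (equal weights).

    Model ids are reassigned sequentially to keep them unique in the pool.
    """
    models = []
    k = 0
    for ens in ensembles:
        for m in ens.models:
            models.append(
                ConformerModel(model_id=k, atoms=m.atoms, plddt=m.plddt, ptm=m.ptm)
            )
            k += 1
    return ConformerEnsemble(label, models)


@dataclass
class ShiftTable:
    """Observed chemical shifts, one row per (chain, residue, atom).

    ``entries`` columns: chain, resnum, restype, atom, shift (ppm).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["chain", "resnum", "restype", "atom", "shift"]
        missing = [c for c in need if c not in self.entries.columns]
        if missing:
            raise ModelIOError(f"shift table missing columns: {missing}")
        self.entries = self.entries[need].copy()
        self.entries["resnum"] = self.entries["resnum"].astype(int)
        self.entries["shift"] = self.entries["shift"].astype(float)
        if not np.all(np.isfinite(self.entries["shift"])):
            raise ModelIOError("non-finite chemical shift")
        dup = self.entries.duplicated(subset=["chain", "resnum", "atom"])
        if dup.any():
            row = self.entries[dup].iloc[0]
            raise ModelIOError(
                f"duplicate shift for {row.chain}:{row.resnum} atom {row.atom}"
            )
        # set semantics: canonical order
        self.entries = self.entries.sort_values(
            ["chain", "resnum", "atom"], kind="mergesort"
        ).reset_index(drop=True)
        self._map = {
            (c, int(r), a): s
            for c, r, a, s in zip(
                self.entries["chain"], self.entries["resnum"],
                self.entries["atom"], self.entries["shift"],
            )
        }

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, chain: str, resnum: int, atom: str) -> float | None:
        return self._map.get((chain, int(resnum), atom))

    def residues(self) -> list[tuple[str, int, str]]:
        sub = self.entries.drop_duplicates(subset=["chain", "resnum"])
        return list(zip(sub["chain"], sub["resnum"], sub["restype"]))


@dataclass
class PeakList:
    """3D NOESY peaks: (w_Hdonor, w_X, w_Hacceptor) in ppm, optional intensity.

    ``spectrum_type`` is ``"N15-NOESY"`` or ``"C13-NOESY"`` and fixes the
    isotope of the heavy atom bonded to the donor proton.
    """

    spectrum_type: str
    peaks: pd.DataFrame

    SPECTRA = ("N15-NOESY", "C13-NOESY")

    def __post_init__(self) -> None:
        if self.spectrum_type not in self.SPECTRA:
            raise ModelIOError(f"unknown spectrum type {self.spectrum_type!r}")
        need = ["peak_id", "w_hdonor", "w_x", "w_hacceptor", "intensity"]
        missing = [c for c in need if c not in self.peaks.columns]
        if missing:
            raise ModelIOError(f"peak list missing columns: {missing}")
        freq = self.peaks[["w_hdonor", "w_x", "w_hacceptor"]].to_numpy(float)
        if not np.all(np.isfinite(freq)):
            raise ModelIOError("non-finite peak frequency")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def heavy_element(self) -> str:
        return "N" if self.spectrum_type == "N15-NOESY" else "C"


# ---------------------------------------------------------------------------
# Ensemble reading / writing
# ---------------------------------------------------------------------------

def read_ensemble(
    path: str | Path,
    fmt: str | None = None,
    ptm_path: str | Path | None = None,
    label: str | None = None,
) -> ConformerEnsemble:
    """Read a multi-model PDB or mmCIF file into a :class:`ConformerEnsemble`.

    Per-residue pLDDT is the mean of the atom B-factors within the residue.
    If every B-factor in the file is ≤ 1.01 the values are assumed to be on
    the 0-1 scale and rescaled to 0-100 with a warning.  pTM is read from
    ``ptm_path`` (default ``<path>.ptm.json``); a missing sidecar assigns the
    neutral prior 1.0 with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such file: {path}")
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise ModelIOError(f"unknown ensemble format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise ModelIOError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ModelIOError(f"{path}: no coordinate models found")

    ptms = _read_ptm_sidecar(path, ptm_path)

    models = []
    all_b: list[float] = []
    raw: list[tuple[int, pd.DataFrame]] = []
    warned_altloc = False
    for i, gm in enumerate(st):
        rows = []
        for chain in gm:
            for res in chain:
                if res.seqid.icode not in (" ", "", "\x00"):
                    raise ModelIOError(
                        f"{path}: insertion code {res.seqid.icode!r} at "
                        f"{chain.name}:{res.seqid.num} unsupported"
                    )
                seen_names = set()
                for atom in res:
                    if atom.name in seen_names:  # later altloc: first wins
                        if not warned_altloc:
                            warnings.warn(
                                f"{path}: alternate locations present; "
                                "keeping the first altloc of each atom"
                            )
                            warned_altloc = True
                        continue
                    seen_names.add(atom.name)
                    rows.append(
                        (
                            chain.name, res.seqid.num, res.name, atom.name,
                            atom.element.name,
                            atom.pos.x, atom.pos.y, atom.pos.z, atom.b_iso,
                        )
                    )
        if not rows:
            raise ModelIOError(f"{path}: model {i + 1} has no atoms")
        df = pd.DataFrame(rows, columns=ATOM_COLUMNS + ["b"])
        all_b.extend(df["b"].tolist())
        raw.append((i + 1, df))

    scale = 1.0
    if all_b and max(all_b) <= 1.01:
        warnings.warn(
            f"{path}: all B-factors <= 1.01; interpreting pLDDT on the 0-1 "
            "scale and rescaling x100"
        )
        scale = 100.0

    for model_id, df in raw:
        plddt = (
            (df.groupby(["chain", "resnum"], sort=False)["b"].mean() * scale)
            .rename("plddt")
        )
        ptm = ptms.get(model_id)
        models.append(
            ConformerModel(
                model_id=model_id,
                atoms=df[ATOM_COLUMNS].reset_index(drop=True),
                plddt=plddt,
                ptm=ptm,
            )
        )
    return ConformerEnsemble(label or path.stem, models)


def _read_ptm_sidecar(path: Path, ptm_path: str | Path | None) -> dict[int, float]:
    candidate = Path(ptm_path) if ptm_path else path.with_name(path.name + ".ptm.json")
    if not candidate.exists():
        warnings.warn(
            f"no pTM sidecar at {candidate}; defaulting pTM to 1.0 (neutral prior)"
        )
        return {}
    data = json.loads(candidate.read_text())
    out = {}
    for k, v in data.items():
        v = float(v)
        if not 0.0 <= v <= 1.0:
            raise ModelIOError(f"{candidate}: pTM {v} outside [0, 1]")
        out[int(k)] = v
    return out


def write_ensemble(
    ens: ConformerEnsemble,
    path: str | Path,
    write_ptm_sidecar: bool = True,
) -> None:
    """Write a multi-MODEL PDB file (B-factor column = per-residue pLDDT)."""
    path = Path(path)
    lines = []
    for m in ens.models:
        lines.append(f"MODEL     {m.model_id:4d}")
        serial = 0
        for row in m.atoms.itertuples(index=False):
            serial += 1
            plddt = float(m.plddt.get((row.chain, row.resnum), 0.0))
            name = row.atom
            # PDB v3 atom-name justification: 1-char elements start in col 14
            if len(name) < 4 and len(row.element) == 1:
                name = " " + name
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {row.resname:<3s} "
                f"{row.chain[:1]}{row.resnum:4d}    "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{1.0:6.2f}{plddt:6.2f}"
                f"          {row.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if write_ptm_sidecar:
        ptms = {m.model_id: (m.ptm if m.ptm is not None else 1.0) for m in ens.models}
        path.with_name(path.name + ".ptm.json").write_text(json.dumps(ptms, indent=1))


# ---------------------------------------------------------------------------
# Chemical-shift tables
# ---------------------------------------------------------------------------

def read_shift_table(path: str | Path, dialect: str = "tsv") -> ShiftTable:
    """Read chemical shifts from a TSV table or an NMR-STAR 3.1 file."""
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such file: {path}")
    if dialect == "tsv":
        return _read_shift_tsv(path)
    if dialect == "nmrstar":
        return _read_shift_nmrstar(path)
    raise ModelIOError(f"unknown shift dialect {dialect!r}")


def _read_shift_tsv(path: Path) -> ShiftTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = ["chain", "residue_number", "residue_type", "atom_name", "shift_ppm"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ModelIOError(f"{path}: missing required column(s) {missing}")
    try:
        resnum = df["residue_number"].astype(int)
        shift = df["shift_ppm"].astype(float)
    except ValueError as exc:
        raise ModelIOError(f"{path}: non-numeric residue number or shift: {exc}")
    return ShiftTable(
        pd.DataFrame(
            {
                "chain": df["chain"],
                "resnum": resnum,
                "restype": df["residue_type"].str.upper(),
                "atom": df["atom_name"].str.upper(),
                "shift": shift,
            }
        )
    )


def _read_shift_nmrstar(path: Path) -> ShiftTable:
    """Minimal NMR-STAR 3.1 reader for the ``Atom_chem_shift`` loop.

    Only the assigned-chemical-shift loop is interpreted; everything else in
    the file is ignored.
    """
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    collecting_tags = False
    for line in path.read_text().splitlines():
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        if tok == "loop_":
            in_loop, collecting_tags, tags = True, True, []
            continue
        if in_loop and collecting_tags and tok.startswith("_"):
            tags.append(tok.split(".")[-1] if "." in tok else tok.lstrip("_"))
            continue
        if in_loop and collecting_tags:
            collecting_tags = False
            if not any(t == "Val" for t in tags) or "Atom_ID" not in tags:
                in_loop = False  # not the shift loop
                tags = []
        if in_loop and not collecting_tags:
            if tok == "stop_":
                in_loop = False
                continue
            vals = tok.split()
            if len(vals) == len(tags):
                rows.append(vals)
    if not tags or not rows:
        raise ModelIOError(f"{path}: no Atom_chem_shift loop found")
    col = {t: i for i, t in enumerate(tags)}

    def _get(row, *names, default=None):
        for n in names:
            if n in col:
                return row[col[n]]
        return default

    out = []
    for row in rows:
        try:
            out.append(
                (
                    _get(row, "Auth_asym_ID", "Entity_assembly_ID", default="A") or "A",
                    int(_get(row, "Seq_ID", "Comp_index_ID")),
                    _get(row, "Comp_ID").upper(),
                    _get(row, "Atom_ID").upper(),
                    float(_get(row, "Val")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ModelIOError(f"{path}: malformed shift row {row}: {exc}")
    df = pd.DataFrame(out, columns=["chain", "resnum", "restype", "atom", "shift"])
    df["chain"] = df["chain"].replace({".": "A", "?": "A", "1": "A"})
    return ShiftTable(df)


def write_shift_table(table: ShiftTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write a shift table in the TSV dialect or as minimal NMR-STAR 3.1."""
    path = Path(path)
    if dialect == "tsv":
        df = table.entries.rename(
            columns={
                "resnum": "residue_number",
                "restype": "residue_type",
                "atom": "atom_name",
                "shift": "shift_ppm",
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    elif dialect == "nmrstar":
        lines = [
            "data_shifts",
            "save_assigned_chem_shift_list_1",
            "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
            "   loop_",
            "      _Atom_chem_shift.ID",
            "      _Atom_chem_shift.Auth_asym_ID",
            "      _Atom_chem_shift.Seq_ID",
            "      _Atom_chem_shift.Comp_ID",
            "      _Atom_chem_shift.Atom_ID",
            "      _Atom_chem_shift.Val",
        ]
        for i, row in enumerate(table.entries.itertuples(index=False), start=1):
            lines.append(
                f"      {i} {row.chain} {row.resnum} {row.restype} "
                f"{row.atom} {row.shift:.3f}"
            )
        lines += ["   stop_", "save_", ""]
        path.write_text("\n".join(lines))
    else:
        raise ModelIOError(f"unknown shift dialect {dialect!r}")


# ---------------------------------------------------------------------------
# NOESY peak lists
# ---------------------------------------------------------------------------

def read_peak_list(path: str | Path, spectrum_type: str) -> PeakList:
    """Read a tab-separated ``w1 w2 w3 [intensity]`` NOESY peak list."""
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such file: {path}")
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        parts = tok.split("\t") if "\t" in tok else tok.split()
        if len(parts) not in (3, 4):
            raise ModelIOError(
                f"{path}: line {lineno}: expected 3 or 4 columns, got {len(parts)}"
            )
        try:
            w = [float(p) for p in parts[:3]]
            inten = float(parts[3]) if len(parts) == 4 else np.nan
        except ValueError:
            raise ModelIOError(f"{path}: line {lineno}: non-numeric value")
        rows.append((len(rows) + 1, w[0], w[1], w[2], inten))
    df = pd.DataFrame(
        rows, columns=["peak_id", "w_hdonor", "w_x", "w_hacceptor", "intensity"]
    )
    return PeakList(spectrum_type=spectrum_type, peaks=df)


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    """Write the TSV peak-list dialect (ppm to 3 decimals)."""
    path = Path(path)
    lines = [f"# {peaks.spectrum_type} peak list: w_Hdonor w_X w_Hacceptor [intensity]"]
    for row in peaks.peaks.itertuples(index=False):
        cells = [f"{row.w_hdonor:.3f}", f"{row.w_x:.3f}", f"{row.w_hacceptor:.3f}"]
        if np.isfinite(row.intensity):
            cells.append(f"{row.intensity:.3f}")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
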