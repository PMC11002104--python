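"""Reading structures and reducing residues to hydrophobicity-carrying points.

Each amino-acid residue is collapsed to a single *effective atom* at the
centroid of its heavy atoms, carrying the residue's intrinsic hydrophobicity
from a configurable scale normalized to [0, 1].  Parsing of PDB/mmCIF is
delegated to gemmi; only the first model is used, waters/ligands are
dropped, and for alternate locations the highest-occupancy conformer of
each atom is kept.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError, UnknownResidueError

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)

# nonstandard -> parent standard residue (spec: map when known, else reject)
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "KCX": "LYS", "CME": "CYS", "FME": "MET",
}


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_id: int
    insertion_code: str | None
    name: str
    heavy_atoms: np.ndarray  # (n_atoms, 3) in Angstrom
    atom_names: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.seq_id}{icode}:{self.name}"

    @property
    def standard_name(self) -> str:
        """The residue's standard 3-letter code (parent for modified residues)."""
        if self.name in STANDARD_RESIDUES:
            return self.name
        return NONSTANDARD_PARENT.get(self.name, self.name)


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]


@dataclass(frozen=True)
class Structure:
    id: str
    chains: tuple[Chain, ...]
    source_format: Literal["pdb", "mmcif"]

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def residues(self) -> Iterable[Residue]:
        for ch in self.chains:
            yield from ch.residues

    @property
    def n_residues(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)


@dataclass(frozen=True)
class EffectiveAtom:
    residue: Residue
    position: np.ndarray  # centroid of the residue's heavy atoms, Angstrom
    h_intrinsic: float    # normalized intrinsic hydrophobicity in [0, 1]


@dataclass(frozen=True)
class HydrophobicityScale:
    """Intrinsic per-residue hydrophobicity, affinely rescaled to [0, 1].

    ``raw`` holds the published values; ``values`` maps each 3-letter code
    to (raw - min) / (max - min) so the least hydrophobic residue is 0 and
    the most hydrophobic is 1.
    """

    name: str
    raw: dict[str, float]
    values: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.raw)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        lo = min(self.raw.values())
        hi = max(self.raw.values())
        if hi == lo:
            raise ValueError(f"scale {self.name!r} is constant; cannot normalize")
        object.__setattr__(
            self, "values", {k: (v - lo) / (hi - lo) for k, v in self.raw.items()}
        )

    def __getitem__(self, residue_name: str) -> float:
        name = residue_name if residue_name in self.values else NONSTANDARD_PARENT.get(residue_name, "")
        try:
            return self.values[name]
        except KeyError:
            raise UnknownResidueError(
                f"residue {residue_name!r} not covered by scale {self.name!r}"
            ) from None


def _parse_scale_text(name: str, text: str) -> HydrophobicityScale:
    raw: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"scale {name!r} line {lineno}: expected '<RES> <value>'")
        raw[parts[0].upper()] = float(parts[1])
    return HydrophobicityScale(name=name, raw=raw)


def load_scale(path: str | Path) -> HydrophobicityScale:
    """Load a scale from a two-column text file (3-letter code, raw value)."""
    p = Path(path)
    return _parse_scale_text(p.stem, p.read_text())


def builtin_scale(name: str = "kyte_doolittle") -> HydrophobicityScale:
    """Load a scale bundled with the package (kyte_doolittle, fauchere_pliska)."""
    ref = importlib.resources.files("fodm.data").joinpath(f"{name}.txt")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValueError(f"no bundled scale named {name!r}") from None
    return _parse_scale_text(name, text)


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.name.lower()
    if suffix.endswith((".cif", ".cif.gz", ".mmcif")):
        return "mmcif"
    return "pdb"


def _best_altloc_atoms(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep, per atom name, the highest-occupancy alternate conformer."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        if atom.is_hydrogen():
            continue
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def parse_structure(path: str | Path, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF file into a first-model, protein-only Structure.

    Waters, ligands and hydrogens are excluded; alternate locations are
    resolved to the highest-occupancy conformer; chains keep file order and
    residues keep author numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = (res.name in STANDARD_RESIDUES or res.name in NONSTANDARD_PARENT
                     or (info is not None and info.is_amino_acid()))
            if not is_aa:
                continue
            atoms = _best_altloc_atoms(res)
            if not atoms:
                continue
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms], dtype=float)
            if not np.all(np.isfinite(coords)):
                raise FormatError(f"{path}: non-finite coordinates in {ch.name}/{res.seqid.num}")
            residues.append(
                Residue(
                    chain_id=ch.name,
                    seq_id=res.seqid.num,
                    insertion_code=(res.seqid.icode.strip() or None),
                    name=res.name,
                    heavy_atoms=coords,
                    atom_names=tuple(a.name for a in atoms),
                )
            )
        if residues:
            chains.append(Chain(chain_id=ch.name, residues=tuple(residues)))

    if not chains:
        raise EmptyStructureError(f"{path}: no protein residues in model 1")
    return Structure(id=path.stem.upper(), chains=tuple(chains),
                     source_format="pdb" if fmt == "pdb" else "mmcif")


def effective_atoms(
    structure: Structure | Iterable[Residue],
    scale: HydrophobicityScale,
    centroid: Literal["heavy", "sidechain"] = "heavy",
) -> list[EffectiveAtom]:
    """One effective atom per residue: heavy-atom centroid + scale value.

    ``centroid='sidechain'`` averages side-chain atoms only (falling back to
    all heavy atoms for glycine); the default averages every heavy atom.
    """
    residues = structure.residues() if isinstance(structure, Structure) else structure
    backbone = {"N", "CA", "C", "O", "OXT"}
    out: list[EffectiveAtom] = []
    for res in residues:
        h = scale[res.name]  # raises UnknownResidueError with the residue name
        coords = res.heavy_atoms
        if centroid == "sidechain" and res.atom_names:
            mask = np.array([n not in backbone for n in res.atom_names])
            if mask.any():  # glycine falls back to all heavy atoms
                coords = res.heavy_atoms[mask]
        out.append(EffectiveAtom(residue=res, position=coords.mean(axis=0), h_intrinsic=h))
    return out
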