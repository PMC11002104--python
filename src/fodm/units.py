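"""Analysis units: whole complexes, chains, domains, partitions, interfaces.

Two granularities mirror how multi-domain proteins are assessed in the
field: an *individual* unit gets its own 3D Gaussian (the subset is treated
as a standalone molecule), while a *component* inherits the Gaussian and
interaction profile of its parent unit, with T and O restricted to the
subset's residues and renormalized.  Interface (P-P) residues are those
whose effective atom lies within a distance threshold of any partner
residue's effective atom; restricted RD values over the P-P and non-P-P
classes diagnose whether an interface is hydrophobic-core-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SelectionError
from .divergence import DEFAULT_K_GRID, DivergenceResult, fit_k
from .field_profiles import (
    DEFAULT_CUTOFF,
    DEFAULT_SIGMA_FLOOR,
    DEFAULT_SIGMA_RULE,
    HydroProfile,
    o_profile,
    orient_unit,
    r_profile,
    t_profile,
)
from .structure_io import (
    EffectiveAtom,
    HydrophobicityScale,
    Structure,
    builtin_scale,
    effective_atoms,
)


@dataclass(frozen=True)
class AnalysisParams:
    """Conventions shared by every analysis; recorded in all provenance."""

    scale: HydrophobicityScale = field(default_factory=builtin_scale)
    cutoff: float = DEFAULT_CUTOFF
    sigma_rule: str = DEFAULT_SIGMA_RULE
    sigma_floor: float = DEFAULT_SIGMA_FLOOR
    k_grid: tuple[float, float, float] = DEFAULT_K_GRID
    interface_threshold: float = DEFAULT_CUTOFF
    include_self: bool = False
    centroid: str = "heavy"

    def provenance(self) -> dict:
        return {
            "scale": self.scale.name,
            "cutoff_A": self.cutoff,
            "sigma_rule": self.sigma_rule,
            "sigma_floor_A": self.sigma_floor,
            "k_grid": list(self.k_grid),
            "interface_threshold_A": self.interface_threshold,
            "include_self": self.include_self,
            "centroid": self.centroid,
        }


@dataclass(frozen=True)
class UnitSelection:
    """A named subset of residues defining one analysis unit.

    ``chain_ids`` selects whole chains; ``residue_ranges`` narrows to
    inclusive author-numbered intervals (chain, start, end).  With neither,
    the selection covers the whole structure.
    """

    label: str
    chain_ids: tuple[str, ...] = ()
    residue_ranges: tuple[tuple[str, int, int], ...] = ()

    def fragment_text(self) -> str:
        if self.residue_ranges:
            return " ".join(f"({s}–{e})" for _, s, e in self.residue_ranges)
        return " ".join(self.chain_ids)

    def mask(self, atoms: Sequence[EffectiveAtom]) -> np.ndarray:
        """Boolean mask of the selection over a list of effective atoms."""
        out = np.zeros(len(atoms), dtype=bool)
        for i, ea in enumerate(atoms):
            res = ea.residue
            if self.residue_ranges:
                for chain, start, end in self.residue_ranges:
                    if res.chain_id == chain and start <= res.seq_id <= end:
                        out[i] = True
                        break
            elif self.chain_ids:
                out[i] = res.chain_id in self.chain_ids
            else:
                out[i] = True
        return out


@dataclass(frozen=True)
class AnalysisRecord:
    """One report row: a unit's RD (with optional P-P split) and K."""

    label: str
    fragment: str
    rd: float
    k: float
    n_residues: int
    rd_pp: float | None = None
    rd_nopp: float | None = None
    n_pp: int | None = None
    mode: str = "individual"
    result: DivergenceResult | None = None
    provenance: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        def fmt(v):
            return "−" if v is None else f"{v:.3f}"
        return {
            "label": self.label,
            "fragment": self.fragment,
            "mode": self.mode,
            "n_residues": self.n_residues,
            "RD": f"{self.rd:.3f}",
            "RD_PP": fmt(self.rd_pp),
            "RD_noPP": fmt(self.rd_nopp),
            "K": f"{self.k:.1f}",
        }


def _unit_arrays(
    source: Structure | Sequence[EffectiveAtom] | "object",
    sel: UnitSelection | None,
    params: AnalysisParams,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Resolve a structure/selection (or a synthetic point cloud) to arrays."""
    if hasattr(source, "points") and hasattr(source, "h"):  # SyntheticUnit duck type
        pts = np.asarray(source.points, dtype=float)
        hv = np.asarray(source.h, dtype=float)
        labels = tuple(str(i + 1) for i in range(len(hv)))
        return pts, hv, labels
    atoms = (
        effective_atoms(source, params.scale, centroid=params.centroid)
        if isinstance(source, Structure)
        else list(source)
    )
    if sel is not None:
        mask = sel.mask(atoms)
        atoms = [a for a, m in zip(atoms, mask) if m]
    if not atoms:
        raise SelectionError(
            f"selection {sel.label if sel else '<all>'!r} resolves to no residues"
        )
    pts = np.array([a.position for a in atoms])
    hv = np.array([a.h_intrinsic for a in atoms])
    labels = tuple(a.residue.label for a in atoms)
    return pts, hv, labels


def _divergence_record(
    o: HydroProfile, t: HydroProfile, params: AnalysisParams
) -> DivergenceResult:
    return fit_k(o, t, grid=params.k_grid, provenance=params.provenance())


def analyze_individual(
    source: Structure | "object",
    sel: UnitSelection | None = None,
    params: AnalysisParams | None = None,
) -> AnalysisRecord:
    """Analyze a unit as a standalone molecule: own Gaussian, own profiles."""
    params = params or AnalysisParams()
    pts, hv, labels = _unit_arrays(source, sel, params)
    if len(hv) < 3:
        raise SelectionError("unit too small: need at least 3 residues")
    unit = orient_unit(pts, hv, labels, sigma_rule=params.sigma_rule,
                       sigma_floor=params.sigma_floor)
    t = t_profile(unit)
    o = o_profile(unit, cutoff_c=params.cutoff, include_self=params.include_self)
    res = _divergence_record(o, t, params)
    label = sel.label if sel is not None else getattr(source, "id", "unit")
    fragment = sel.fragment_text() if sel is not None else ""
    return AnalysisRecord(
        label=str(label), fragment=fragment, rd=res.rd, k=res.k_reported,
        n_residues=len(hv), mode="individual", result=res,
        provenance=params.provenance(),
    )


def _restricted_profiles(
    t: HydroProfile, o: HydroProfile, idx: np.ndarray
) -> tuple[HydroProfile, HydroProfile, HydroProfile]:
    """Restrict parent T and O to a residue subset and renormalize."""
    labels = tuple(np.asarray(t.labels, dtype=object)[idx]) if t.labels else ()
    tv = t.values[idx]
    ov = o.values[idx]
    t_sub = HydroProfile(role="T", values=tv / tv.sum(), labels=labels)
    o_sub = HydroProfile(role="O", values=ov / ov.sum(), labels=labels)
    r_sub = r_profile(idx.size, labels=labels or None)
    return t_sub, o_sub, r_sub


def analyze_component(
    structure: Structure,
    parent: UnitSelection,
    sub: UnitSelection,
    params: AnalysisParams | None = None,
) -> AnalysisRecord:
    """Analyze ``sub`` as a component of ``parent``.

    The Gaussian and the interaction profile are those of the parent;
    T and O are restricted to the sub-selection and renormalized, and the
    uniform reference runs over the subset only.
    """
    params = params or AnalysisParams()
    pts, hv, labels = _unit_arrays(structure, parent, params)
    unit = orient_unit(pts, hv, labels, sigma_rule=params.sigma_rule,
                       sigma_floor=params.sigma_floor)
    t = t_profile(unit)
    o = o_profile(unit, cutoff_c=params.cutoff, include_self=params.include_self)

    atoms = effective_atoms(structure, params.scale, centroid=params.centroid)
    parent_mask = parent.mask(atoms)
    sub_mask = sub.mask(atoms)
    if np.any(sub_mask & ~parent_mask):
        raise SelectionError(f"{sub.label!r} is not contained in {parent.label!r}")
    idx = np.nonzero(sub_mask[parent_mask])[0]
    if idx.size < 3:
        raise SelectionError(f"{sub.label!r} resolves to fewer than 3 residues")
    t_sub, o_sub, _ = _restricted_profiles(t, o, idx)
    res = _divergence_record(o_sub, t_sub, params)
    return AnalysisRecord(
        label=sub.label, fragment=sub.fragment_text(), rd=res.rd,
        k=res.k_reported, n_residues=idx.size, mode="component",
        result=res, provenance=params.provenance(),
    )


def interface_residues(
    structure: Structure,
    target: UnitSelection,
    partners: UnitSelection,
    threshold: float | None = None,
    params: AnalysisParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the target's residues into (PP, noPP) boolean masks.

    A residue is P-P when its effective atom lies within ``threshold`` (<=,
    default the interaction cutoff) of any partner residue's effective atom.
    The two masks are exhaustive and disjoint over the target selection.
    """
    params = params or AnalysisParams()
    threshold = params.interface_threshold if threshold is None else threshold
    atoms = effective_atoms(structure, params.scale, centroid=params.centroid)
    t_mask = target.mask(atoms)
    p_mask = partners.mask(atoms)
    if np.any(t_mask & p_mask):
        raise SelectionError("partner selection overlaps the target")
    t_pos = np.array([a.position for a, m in zip(atoms, t_mask) if m])
    p_pos = np.array([a.position for a, m in zip(atoms, p_mask) if m])
    if p_pos.size == 0:
        pp = np.zeros(t_pos.shape[0], dtype=bool)
    else:
        d = np.sqrt(((t_pos[:, None, :] - p_pos[None, :, :]) ** 2).sum(-1))
        pp = (d <= threshold).any(axis=1)
    return pp, ~pp


def analyze_with_interface(
    structure: Structure,
    target: UnitSelection,
    partners: UnitSelection | None,
    params: AnalysisParams | None = None,
    parent: UnitSelection | None = None,
) -> AnalysisRecord:
    """Full-unit RD/K plus restricted RD over P-P and non-P-P residues.

    The full record is computed individually on the target (or in component
    mode under ``parent``); the P-P / no-P-P values always come from
    component-style restriction of the target's own T and O.  An empty
    class leaves the corresponding field absent (reported as a dash).
    """
    params = params or AnalysisParams()
    if parent is not None:
        base = analyze_component(structure, parent, target, params)
    else:
        base = analyze_individual(structure, target, params)
    if partners is None:
        return base

    pts, hv, labels = _unit_arrays(structure, target, params)
    unit = orient_unit(pts, hv, labels, sigma_rule=params.sigma_rule,
                       sigma_floor=params.sigma_floor)
    t = t_profile(unit)
    o = o_profile(unit, cutoff_c=params.cutoff, include_self=params.include_self)
    pp, nopp = interface_residues(structure, target, partners, params=params)

    def class_rd(mask: np.ndarray) -> float | None:
        idx = np.nonzero(mask)[0]
        if idx.size == mask.size:
            return base.rd          # the class is the whole unit
        if idx.size < 2:
            return None             # empty or single-residue class -> dash
        t_sub, o_sub, r_sub = _restricted_profiles(t, o, idx)
        from .divergence import rd_statistic
        return rd_statistic(o_sub, t_sub, r_sub)

    rd_pp = class_rd(pp) if pp.any() else None
    rd_nopp = class_rd(nopp) if nopp.any() else None
    return AnalysisRecord(
        label=base.label, fragment=base.fragment, rd=base.rd, k=base.k,
        n_residues=base.n_residues, rd_pp=rd_pp, rd_nopp=rd_nopp,
        n_pp=int(pp.sum()), mode=base.mode, result=base.result,
        provenance=base.provenance,
    )


def analyze_complex(
    structure: Structure,
    part_definitions: Sequence[UnitSelection] = (),
    params: AnalysisParams | None = None,
    chains: Sequence[str] | None = None,
) -> list[AnalysisRecord]:
    """Complex-level report: whole complex, each chain twice, named parts.

    Emits one record for the whole complex (all selected chains as one
    individual unit), one component-mode and one individual-mode record per
    chain, and one component-mode record per named partition (e.g. a
    beta-sheet stem or the helical tentacles, supplied as residue ranges).
    """
    params = params or AnalysisParams()
    chain_ids = tuple(chains) if chains else tuple(ch.chain_id for ch in structure.chains)
    whole = UnitSelection(label=f"{structure.id} complex", chain_ids=chain_ids)
    records = [analyze_individual(structure, whole, params)]
    for cid in chain_ids:
        chain_sel = UnitSelection(label=f"Chain {cid}", chain_ids=(cid,))
        rec = analyze_component(structure, whole, chain_sel, params)
        records.append(replace(rec, label=f"Chain {cid} (in complex)"))
        records.append(analyze_individual(structure, chain_sel, params))
    for part in part_definitions:
        records.append(analyze_component(structure, whole, part, params))
    return records


def profile_table(
    source: Structure | "object",
    sel: UnitSelection | None = None,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Per-residue T/O/R/M table for one unit, M evaluated at the fitted K.

    Columns: chain, seq_id, residue_name, T, O, R, M — the data behind the
    standard profile line plots.
    """
    from .field_profiles import m_profile

    params = params or AnalysisParams()
    pts, hv, labels = _unit_arrays(source, sel, params)
    unit = orient_unit(pts, hv, labels, sigma_rule=params.sigma_rule,
                       sigma_floor=params.sigma_floor)
    t = t_profile(unit)
    o = o_profile(unit, cutoff_c=params.cutoff, include_self=params.include_self)
    res = fit_k(o, t, grid=params.k_grid)
    m = m_profile(t, res.k_fit)
    r = r_profile(len(t))
    chain, seq, name = [], [], []
    for lbl in labels:
        parts = lbl.split(":")
        if len(parts) == 3:
            chain.append(parts[0]); seq.append(parts[1]); name.append(parts[2])
        else:
            chain.append(""); seq.append(lbl); name.append("")
    return pd.DataFrame({
        "chain": chain, "seq_id": seq, "residue_name": name,
        "T": t.values, "O": o.values, "R": r.values, "M": m.values,
    })


def records_to_tsv(records: Sequence[AnalysisRecord], path: str | Path | None = None) -> pd.DataFrame:
    """Tabulate records in report-table column order; optionally write TSV."""
    df = pd.DataFrame([r.to_row() for r in records])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
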