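"""Delimited-text readers/writers, FASTA input, and result serialization.

Units are declared in column headers rather than guessed: a melt table
carries ``T_K`` or ``T_C`` plus ``signal``; a denaturation table
``denat_M`` plus ``signal``; a thermogram ``T_K``/``T_C`` plus
``Cp_kJ_K_mol``; CEST tables the per-point schema below.  Ambiguous or
missing headers are an error naming the file and column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cest import CESTProfile
from .dsc import Thermogram
from .thermo import celsius_to_kelvin
from .unfolding import AxisKind, Technique, UnfoldingCurve

__all__ = [
    "read_unfolding_table",
    "write_unfolding_table",
    "read_thermogram",
    "write_thermogram",
    "read_cest_table",
    "write_cest_table",
    "read_shift_table",
    "read_fasta",
    "ResultRecord",
    "write_results",
]

CEST_COLUMNS = ["residue", "nucleus", "B0_MHz", "nu1_Hz", "Tex_s", "offset_ppm", "intensity_ratio"]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: unparseable number in column {col!r}, row {row}")
    return vals.to_numpy(dtype=float)


def read_unfolding_table(
    path: str | Path,
    technique: Technique | str = Technique.CD_far_UV,
    axis_kind: AxisKind | str | None = None,
) -> UnfoldingCurve:
    """Read a melt or chemical-denaturation curve.

    Columns: ``T_K`` or ``T_C`` (melt) or ``denat_M`` (chemical), and
    ``signal``; an optional ``replicate`` column is averaged per x.
    """
    path = Path(path)
    df = _read_delimited(path)
    if "signal" not in df.columns:
        raise ValueError(f"{path}: missing required column 'signal'")
    axis_cols = [c for c in ("T_K", "T_C", "denat_M") if c in df.columns]
    if len(axis_cols) != 1:
        raise ValueError(
            f"{path}: need exactly one axis column of T_K/T_C/denat_M, found {axis_cols}"
        )
    col = axis_cols[0]
    x = _numeric(df, col, path)
    if col == "T_C":
        x = celsius_to_kelvin(x)
    if col == "denat_M":
        kind = AxisKind(axis_kind) if axis_kind is not None else AxisKind.urea
        if kind is AxisKind.temperature:
            raise ValueError(f"{path}: denat_M column conflicts with temperature axis")
    else:
        kind = AxisKind.temperature
        if axis_kind is not None and AxisKind(axis_kind) is not kind:
            raise ValueError(f"{path}: {col} column conflicts with axis_kind={axis_kind}")
    signal = _numeric(df, "signal", path)
    return UnfoldingCurve(x=x, signal=signal, technique=Technique(technique), axis_kind=kind)


def write_unfolding_table(curve: UnfoldingCurve, path: str | Path) -> None:
    path = Path(path)
    col = "T_K" if curve.axis_kind is AxisKind.temperature else "denat_M"
    df = pd.DataFrame({col: curve.x, "signal": curve.signal})
    df.to_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",", index=False)


def read_thermogram(path: str | Path) -> Thermogram:
    """Read a molar-normalized thermogram (T_K or T_C, Cp_kJ_K_mol)."""
    path = Path(path)
    df = _read_delimited(path)
    if "Cp_kJ_K_mol" not in df.columns:
        raise ValueError(f"{path}: missing required column 'Cp_kJ_K_mol'")
    axis_cols = [c for c in ("T_K", "T_C") if c in df.columns]
    if len(axis_cols) != 1:
        raise ValueError(f"{path}: need exactly one of T_K/T_C, found {axis_cols}")
    T = _numeric(df, axis_cols[0], path)
    if axis_cols[0] == "T_C":
        T = celsius_to_kelvin(T)
    return Thermogram(T=T, Cp=_numeric(df, "Cp_kJ_K_mol", path))


def write_thermogram(tg: Thermogram, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"T_K": tg.T, "Cp_kJ_K_mol": tg.Cp}).to_csv(
        path, sep="\t" if path.suffix.lower() == ".tsv" else ",", index=False
    )


def read_cest_table(path: str | Path) -> dict[str, list[CESTProfile]]:
    """Read long-format CEST data into per-residue profile lists."""
    path = Path(path)
    df = _read_delimited(path)
    missing = [c for c in CEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: dict[str, list[CESTProfile]] = {}
    keys = ["residue", "nucleus", "B0_MHz", "nu1_Hz", "Tex_s"]
    for (rid, nuc, b0, nu1, tex), grp in df.groupby(keys, sort=True):
        out.setdefault(str(rid), []).append(
            CESTProfile(
                residue=str(rid),
                offsets_ppm=_numeric(grp.reset_index(drop=True), "offset_ppm", path),
                intensity_ratio=_numeric(grp.reset_index(drop=True), "intensity_ratio", path),
                nu1_Hz=float(nu1),
                larmor_MHz=float(b0),
                Tex_s=float(tex),
                nucleus=str(nuc),
            )
        )
    return out


def write_cest_table(profiles_by_residue: dict, path: str | Path) -> None:
    rows = []
    for rid, profiles in profiles_by_residue.items():
        for p in profiles:
            for off, inten in zip(p.offsets_ppm, p.intensity_ratio):
                rows.append(
                    dict(
                        residue=rid,
                        nucleus=p.nucleus,
                        B0_MHz=p.larmor_MHz,
                        nu1_Hz=p.nu1_Hz,
                        Tex_s=p.Tex_s,
                        offset_ppm=off,
                        intensity_ratio=inten,
                    )
                )
    path = Path(path)
    pd.DataFrame(rows, columns=CEST_COLUMNS).to_csv(
        path, sep="\t" if path.suffix.lower() == ".tsv" else ",", index=False
    )


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read a chemical-shift table (residue, residue_type, atom, ppm).

    ppm values pass through bit-exact; no rounding or unit conversion.
    """
    path = Path(path)
    df = _read_delimited(path)
    required = ["residue", "atom", "ppm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.copy()
    df["residue"] = df["residue"].astype(int)
    df["ppm"] = _numeric(df, "ppm", path)
    return df


VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(path: str | Path, index: int | None = None) -> str:
    """Read one protein sequence from a FASTA file (uppercased, validated)."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1 and index is None:
        raise ValueError(f"{path}: {len(records)} records; specify an index")
    rec = records[index or 0]
    seq = str(rec.seq).upper()
    bad = sorted(set(seq) - VALID_RESIDUES)
    if bad:
        raise ValueError(f"{path}: illegal residue(s) {bad} in record {rec.id!r}")
    return seq


@dataclasses.dataclass
class ResultRecord:
    """A serializable analysis result with provenance."""

    analysis: str
    parameters: dict[str, Any]
    errors: dict[str, Any]
    diagnostics: dict[str, Any]
    input_digest: str | None = None
    seed: int | None = None
    version: str = __version__
    model: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def digest_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(records: list[ResultRecord] | ResultRecord, path: str | Path) -> None:
    if isinstance(records, ResultRecord):
        records = [records]
    payload = [r.to_dict() for r in records]
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
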