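"""Plain-text readers and writers plus strict run configuration.

Formats (all tab-separated, deterministic column order, floats at 10
significant digits):

* genotypes: ``id`` + one column per marker, dosages 0/1/2 (``tsv-dosage``),
  or the PLINK ``.raw`` dialect with FID/IID/PAT/MAT/SEX/PHENOTYPE leading
  columns; missing genotypes are rejected, not imputed
* pedigree: ``id  sire  dam`` with ``0`` for unknown parents
* phenotypes: ``id  family  site  block  <trait columns>``
* map: ``marker  chromosome  position_cM`` (a comment line preserves exact
  chromosome lengths)

An optional single-file HDF5 bundle stores a whole simulated trial.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gmap import GeneticMap
from .pedigree import PedigreeTable
from .rrblup import MarkerMatrix

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_map",
    "write_map",
    "write_trial",
    "write_hdf5_bundle",
    "RunConfig",
    "write_provenance",
]

_FLOAT_FMT = "%.10g"
_PLINK_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _fail(path, lineno, msg):
    raise ValueError(f"{path}:{lineno}: {msg}")


def read_genotype_matrix(path, dialect: str = "tsv-dosage") -> MarkerMatrix:
    """Read a dosage matrix; values outside {0,1,2} are rejected with line numbers."""
    path = Path(path)
    if dialect not in ("tsv-dosage", "plink-raw"):
        raise ValueError("dialect must be 'tsv-dosage' or 'plink-raw'")
    sep = "\t" if dialect == "tsv-dosage" else r"\s+"
    lead = 1 if dialect == "tsv-dosage" else len(_PLINK_LEAD)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: no records in genotype file")
    header = lines[0].split("\t") if dialect == "tsv-dosage" else lines[0].split()
    if len(header) <= lead:
        raise ValueError(f"{path}: genotype header has no marker columns")
    if dialect == "plink-raw" and header[: len(_PLINK_LEAD)] != _PLINK_LEAD:
        raise ValueError(f"{path}: not a PLINK .raw header (expected {_PLINK_LEAD})")
    marker_ids = header[lead:]
    ids, rows = [], []
    seen = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t") if dialect == "tsv-dosage" else ln.split()
        if len(parts) != len(header):
            _fail(path, lineno, f"ragged row: {len(parts)} fields, expected {len(header)}")
        iid = parts[0] if dialect == "tsv-dosage" else parts[1]
        if iid in seen:
            _fail(path, lineno, f"duplicate individual id {iid!r}")
        seen.add(iid)
        vals = np.empty(len(marker_ids))
        for j, tok in enumerate(parts[lead:]):
            if tok in ("NA", "", "."):
                _fail(path, lineno, f"missing genotype for marker {marker_ids[j]!r}")
            try:
                v = float(tok)
            except ValueError:
                _fail(path, lineno, f"non-numeric dosage {tok!r}")
            if v not in (0.0, 1.0, 2.0):
                _fail(path, lineno, f"dosage {tok!r} not in {{0,1,2}}")
            vals[j] = v
        ids.append(iid)
        rows.append(vals)
    return MarkerMatrix(np.vstack(rows), ids, marker_ids)


def write_genotype_matrix(path, M: MarkerMatrix, dialect: str = "tsv-dosage") -> None:
    path = Path(path)
    X = M.values
    if M.is_centered:
        raise ValueError("refusing to write a centred matrix as dosages")
    Xi = X.astype(int)
    with open(path, "w") as fh:
        if dialect == "tsv-dosage":
            fh.write("id\t" + "\t".join(M.marker_ids) + "\n")
            for iid, row in zip(M.ids, Xi):
                fh.write(iid + "\t" + "\t".join(map(str, row)) + "\n")
        elif dialect == "plink-raw":
            fh.write(" ".join(_PLINK_LEAD + list(M.marker_ids)) + "\n")
            for iid, row in zip(M.ids, Xi):
                fh.write(f"{iid} {iid} 0 0 0 -9 " + " ".join(map(str, row)) + "\n")
        else:
            raise ValueError("dialect must be 'tsv-dosage' or 'plink-raw'")


def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column pedigree; reordering is attempted, cycles are errors."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no records in pedigree file")
    if list(df.columns[:3]) != ["id", "sire", "dam"]:
        raise ValueError(f"{path}: expected header 'id\\tsire\\tdam'")
    return PedigreeTable.from_records(df[["id", "sire", "dam"]].itertuples(index=False, name=None))


def write_pedigree(path, ped: PedigreeTable) -> None:
    ped.to_dataframe().to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "family": str, "site": str, "block": str})
    if df.empty:
        raise ValueError(f"{path}: no records in phenotype file")
    for col in ("id", "site", "block"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table lacks required column {col!r}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r} in phenotype table")
    return df


def write_phenotypes(path, phen: pd.DataFrame, columns=None) -> None:
    if columns is None:
        lead = [c for c in ("id", "family", "site", "block") if c in phen.columns]
        rest = [c for c in phen.columns if c not in lead]
        columns = lead + rest
    phen[columns].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_map(path) -> GeneticMap:
    path = Path(path)
    lengths = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#chromosome_lengths_cM:"):
            lengths = np.array(
                [float(v) for v in first.split(":", 1)[1].split(",")], dtype=float
            )
            df = pd.read_csv(fh, sep="\t", dtype={"marker": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"marker": str})
    if df.empty:
        raise ValueError(f"{path}: no records in map file")
    for col in ("marker", "chromosome", "position_cM"):
        if col not in df.columns:
            raise ValueError(f"{path}: map table lacks required column {col!r}")
    chrom = df["chromosome"].to_numpy(int) - 1
    if lengths is None:
        n_chrom = chrom.max() + 1
        lengths = np.array(
            [df.loc[chrom == c, "position_cM"].max() for c in range(n_chrom)], dtype=float
        )
    order = np.lexsort((df["position_cM"].to_numpy(), chrom))
    df = df.iloc[order]
    return GeneticMap(lengths, chrom[order], df["position_cM"].to_numpy(float),
                      list(df["marker"]))


def write_map(path, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chromosome_lengths_cM:"
            + ",".join(_FLOAT_FMT % v for v in gmap.chrom_lengths)
            + "\n"
        )
        gmap.to_dataframe().to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_trial(outdir, trial, write_plink: bool = False) -> dict:
    """Write a simulated trial as the four plain-text tables.

    The genotype table holds the observable SNP panel (QTLs excluded when
    the architecture says so) for the offspring. Returns the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = trial.population
    panel_idx, X = trial.panel_dosages()
    marker_ids = [pop.gmap.marker_ids[i] for i in panel_idx]
    M = MarkerMatrix(X.astype(float), list(pop.offspring_ids), marker_ids)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "map": outdir / "map.tsv",
    }
    write_genotype_matrix(paths["genotypes"], M,
                          "plink-raw" if write_plink else "tsv-dosage")
    write_pedigree(paths["pedigree"], pop.pedigree_table())
    write_phenotypes(paths["phenotypes"], trial.phenotypes,
                     columns=["id", "family", "site", "block", "y"])
    write_map(paths["map"], pop.gmap)
    return paths


def write_hdf5_bundle(path, trial) -> None:
    """Single-file HDF5 bundle of a simulated trial (optional convenience)."""
    import h5py

    pop = trial.population
    with h5py.File(path, "w") as f:
        f.create_dataset("haplotypes", data=pop.haplotypes, compression="gzip")
        f.create_dataset("founder_freqs", data=pop.founder_freqs)
        f.create_dataset("map/chrom_lengths", data=pop.gmap.chrom_lengths)
        f.create_dataset("map/chrom", data=pop.gmap.chrom)
        f.create_dataset("map/pos_cm", data=pop.gmap.pos_cm)
        str_dt = h5py.string_dtype()
        f.create_dataset("map/marker_ids", data=list(pop.gmap.marker_ids), dtype=str_dt)
        f.create_dataset("ids", data=list(pop.ids), dtype=str_dt)
        f.create_dataset("sires", data=list(pop.sires), dtype=str_dt)
        f.create_dataset("dams", data=list(pop.dams), dtype=str_dt)
        f.create_dataset("realized_sires", data=list(pop.realized_sires), dtype=str_dt)
        f.attrs["n_founders"] = pop.n_founders
        f.attrs["design_kind"] = pop.design.kind
        phen = trial.phenotypes
        for col in phen.columns:
            data = phen[col].to_numpy()
            if data.dtype == object:
                f.create_dataset(f"phenotypes/{col}", data=list(map(str, data)), dtype=str_dt)
            else:
                f.create_dataset(f"phenotypes/{col}", data=data)


_SIM_KEYS = {
    "kind", "n_families", "offspring_per_family", "n_markers", "n_qtl",
    "n_chromosomes", "total_length_cm", "maf_min", "n_parents",
    "pollen_pool_size", "n_sites", "blocks_per_site", "urn_alpha",
    "sa_structure", "exclude_qtl_from_panel", "variance_components",
}


@dataclass(frozen=True)
class RunConfig:
    """Strictly parsed run configuration (unknown keys are rejected)."""

    seed: int = 0
    out: str = "gslab-out"
    verbosity: str = "info"
    simdata: dict | None = None
    experiment: dict | None = None

    def __post_init__(self):
        if self.simdata:
            unknown = set(self.simdata) - _SIM_KEYS
            if unknown:
                raise ValueError(f"unknown simdata keys: {sorted(unknown)}")
        if self.experiment:
            allowed = {f.name for f in dc_fields(__import__(
                "gslab.experiment", fromlist=["ExperimentConfig"]).ExperimentConfig)}
            allowed |= {"designs", "reml_tol", "reml_maxiter"}
            unknown = set(self.experiment) - allowed
            if unknown:
                raise ValueError(f"unknown experiment keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        allowed = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_provenance(outdir, config: dict, seed: int) -> Path:
    """Record config hash, seed and package version alongside the outputs."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    info = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "gslab_version": __version__,
    }
    path = outdir / "run_info.json"
    path.write_text(json.dumps(info, indent=2, sort_keys=True) + "\n")
    return path
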