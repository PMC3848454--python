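"""File formats, validation, configuration, and run-metadata plumbing.

Everything is plain tab-delimited text at the scale of this analysis
(hundreds of lines x hundreds of markers):

* genotypes — first column ``line_id``, one column per marker, cells
  0/1/2 with ``NA`` (or ``.``) for missing;
* map — columns ``marker, chrom, pos_cM``;
* phenotypes — long format ``line_id, location_id, value``;
* membership — ``line_id, group``.

Floats are written with 6 significant digits and deterministic column
order so identical runs diff cleanly.  Every stochastic stage derives its
seed from one master seed plus the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GeneticMap, MarkerMatrix, PhenotypeRecords

__all__ = [
    "RunConfig",
    "Dataset",
    "derive_seed",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "read_membership",
    "write_membership",
    "read_dataset",
    "write_dataset",
    "write_results",
]

logger = logging.getLogger(__name__)

_MISSING = {"NA", ".", "", "nan", "NaN"}
FLOAT_FMT = "%.6g"


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed (always < 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """End-to-end run configuration; every stage seed derives from ``seed``."""

    seed: int = 0
    traits: tuple[str, ...] = ("WSY", "SC", "RY", "Na", "K", "N")
    h_convention: str = "training"  # "training" | "per-group"
    l_convention: str = "harmonic"
    lambda_source: str = "full-data"  # "full-data" | "per-fold"
    imputation_mode: str = "sample"
    cv_k: int = 5
    cv_repeats: int = 100
    cv_mode: str = "partition"
    out_dir: str = "results"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["traits"] = list(d["traits"])
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class Dataset:
    """Jointly validated bundle: genotypes, map, phenotypes, membership."""

    genotypes: MarkerMatrix
    gmap: GeneticMap
    phenotypes: dict[str, PhenotypeRecords] = field(default_factory=dict)
    membership: pd.Series | None = None


# ---------------------------------------------------------------------------
# readers / writers


def write_genotypes(mm: MarkerMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mm.X, columns=mm.marker_ids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "line_id", mm.line_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "line_id":
        raise ValueError("genotype file must start with a 'line_id' column")
    line_ids = df["line_id"].to_numpy(dtype=object)
    dup = pd.Series(line_ids).duplicated()
    if dup.any():
        raise ValueError(f"duplicate line_id in genotypes: {line_ids[dup.to_numpy()][0]}")
    marker_ids = df.columns[1:].to_numpy(dtype=object)
    X = np.empty((len(df), len(marker_ids)))
    for j, mk in enumerate(marker_ids):
        col = df[mk].to_numpy()
        for i, cell in enumerate(col):
            if cell in _MISSING:
                X[i, j] = np.nan
            elif cell in ("0", "1", "2"):
                X[i, j] = float(cell)
            else:
                raise ValueError(
                    f"invalid dosage '{cell}' at line {line_ids[i]!r}, marker {mk!r} "
                    "(expected 0/1/2/NA)"
                )
    return MarkerMatrix(X, line_ids, marker_ids)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    required = {"marker", "chrom", "pos_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"map file needs columns {sorted(required)}")
    return GeneticMap(
        df["marker"].to_numpy(dtype=object),
        df["chrom"].to_numpy(),
        df["pos_cM"].to_numpy(dtype=float),
    )


def write_phenotypes(records: PhenotypeRecords, path: str | Path) -> None:
    records.df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_phenotypes(path: str | Path, trait: str = "trait") -> PhenotypeRecords:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeRecords(df, trait=trait)


def write_membership(membership: pd.Series, path: str | Path) -> None:
    membership.rename("group").rename_axis("line_id").to_frame().to_csv(path, sep="\t")


def read_membership(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["line_id", "group"]:
        raise ValueError("membership file needs columns line_id, group")
    return pd.Series(df["group"].to_numpy(), index=pd.Index(df["line_id"], name="line_id"),
                     name="group")


def read_dataset(
    genotypes: str | Path,
    gmap: str | Path,
    phenotypes: dict[str, str | Path] | None = None,
    membership: str | Path | None = None,
) -> Dataset:
    """Read and cross-validate a full dataset.

    Marker ids must agree between genotype matrix and map; phenotyped
    lines absent from the genotypes are dropped with a logged count.
    """
    mm = read_genotypes(genotypes)
    gm = read_map(gmap)
    if list(mm.marker_ids) != list(gm.marker_ids):
        raise ValueError("marker ids differ between genotype matrix and map")
    phenos: dict[str, PhenotypeRecords] = {}
    genotyped = set(mm.line_ids)
    for trait, path in (phenotypes or {}).items():
        rec = read_phenotypes(path, trait=trait)
        known = rec.df["line_id"].isin(genotyped)
        n_drop = rec.df.loc[~known, "line_id"].nunique()
        if n_drop:
            logger.warning("trait %s: dropped %d phenotyped lines without genotypes",
                           trait, n_drop)
            rec = PhenotypeRecords(rec.df[known].reset_index(drop=True), trait=trait)
        phenos[trait] = rec
    member = read_membership(membership) if membership is not None else None
    if member is not None:
        member = member[member.index.isin(genotyped)]
    return Dataset(mm, gm, phenos, member)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "map": out / "map.tsv",
    }
    write_genotypes(ds.genotypes, paths["genotypes"])
    write_map(ds.gmap, paths["map"])
    for trait, rec in ds.phenotypes.items():
        p = out / f"pheno_{trait}.tsv"
        write_phenotypes(rec, p)
        paths[f"pheno_{trait}"] = p
    if ds.membership is not None:
        paths["membership"] = out / "membership.tsv"
        write_membership(ds.membership, paths["membership"])
    return paths


def write_results(
    results: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
    force: bool = True,
) -> Path:
    """Write a result table as TSV plus a JSON run-metadata sidecar.

    Column order is preserved, floats use 6 significant digits, and the
    sidecar (``<name>.meta.json``) records whatever the caller supplies
    (seeds, config hash, convergence info).
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"refusing to overwrite {path} (force=False)")
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    if metadata is not None:
        side = path.with_suffix(path.suffix + ".meta.json")
        side.write_text(json.dumps(metadata, indent=2, sort_keys=True, default=str) + "\n")
    return path
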