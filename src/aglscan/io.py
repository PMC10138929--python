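"""Readers and writers for the plain-text pipeline formats.

Genotypes: tab-separated animals x SNPs code matrix (header row of SNP ids,
first column the animal id) or PLINK ``.raw`` additive coding; missing is
NA.  Phenotypes and pedigree are CSV, the SNP map and all result tables are
TSV.  Every writer produces a file its paired reader parses back to an
equal in-memory object.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .agls import PhenotypeTable
from .blup import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "read_snp_map",
    "write_snp_map",
    "read_results",
    "write_results",
    "export_manhattan",
    "write_population",
]

PathLike = Union[str, Path]
_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _validate_codes(df: pd.DataFrame, path: PathLike) -> pd.DataFrame:
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    ok = np.isnan(numeric) & pd.isna(values.ravel()) | np.isin(numeric, (0.0, 1.0, 2.0))
    # entries that failed numeric conversion but are not genuinely missing
    bad_nonnumeric = np.isnan(numeric) & ~pd.isna(values.ravel())
    is_na_token = np.isin(
        np.char.upper(values.ravel().astype(str)), ("NA", "NAN", "")
    )
    bad = (~ok | bad_nonnumeric) & ~is_na_token
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        row, col = divmod(flat, df.shape[1])
        raise ValueError(
            f"{path}: invalid genotype code {values[row, col]!r} for animal "
            f"{df.index[row]!r}, SNP {df.columns[col]!r} (expected 0/1/2/NA)"
        )
    out = pd.DataFrame(
        numeric.reshape(values.shape), index=df.index, columns=df.columns
    )
    out[bad_nonnumeric.reshape(values.shape) | np.isnan(
        numeric.reshape(values.shape)
    )] = np.nan
    return out


def read_genotypes(path: PathLike) -> pd.DataFrame:
    """Genotype code matrix from TSV or PLINK .raw; codes {0,1,2,NaN}.

    The returned DataFrame is indexed by animal id with one float column
    per SNP; `.raw` counted-allele suffixes (``rs123_A``) are stripped from
    SNP names.
    """
    path = Path(path)
    if path.suffix == ".raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in ("FID", "IID") if c not in df.columns]
        if missing_meta:
            raise ValueError(f"{path}: not a PLINK .raw file (no {missing_meta})")
        df = df.set_index("IID")
        df = df.drop(columns=[c for c in _RAW_META_COLS if c in df.columns])
        df.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in df.columns]
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "animal"
    return _validate_codes(df, path)


def write_genotypes(genotypes: pd.DataFrame, path: PathLike) -> None:
    out = genotypes.copy()
    out.index.name = "animal"
    # integer rendering where nothing is missing keeps files compact
    if not out.isna().any().any():
        out = out.astype(int)
    out.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path: PathLike) -> PhenotypeTable:
    """Phenotype CSV with columns animal_id, y[, a_tilde] (a_tilde: 2*PTA)."""
    df = pd.read_csv(path)
    if "animal_id" not in df.columns or "y" not in df.columns:
        raise ValueError(f"{path}: phenotype file needs columns animal_id, y")
    return PhenotypeTable.from_dataframe(df)


def write_phenotypes(table: PhenotypeTable, path: PathLike) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_pedigree(path: PathLike) -> Pedigree:
    """3-column CSV (animal, sire, dam); 0 or NA marks an unknown parent."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pedigree needs columns animal, sire, dam")
    records = list(df.iloc[:, :3].itertuples(index=False, name=None))
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path: PathLike) -> None:
    def label(idx: int):
        return ped.ids[idx] if idx >= 0 else 0

    pd.DataFrame(
        {
            "animal": list(ped.ids),
            "sire": [label(s) for s in ped.sire],
            "dam": [label(d) for d in ped.dam],
        }
    ).to_csv(path, index=False)


def read_snp_map(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"snp", "chr", "pos"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: SNP map needs columns {sorted(needed)}")
    return df


def write_snp_map(snp_map: pd.DataFrame, path: PathLike) -> None:
    snp_map.to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: PathLike) -> None:
    """Scan results TSV mirroring the reporting-table column semantics."""
    results.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def _chrom_sort_key(chrom) -> tuple:
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def export_manhattan(
    results: pd.DataFrame,
    path: PathLike,
    plot_path: Optional[PathLike] = None,
) -> pd.DataFrame:
    """Plot-ready long table (chrom, position, neglog10p, test) for any
    plotting tool; chromosomes ordered numerically then lexically.

    ``plot_path`` additionally renders a simple two-panel scatter.
    """
    rows = []
    for test, col in (
        ("additive", "neglog10p_additive"),
        ("dominance", "neglog10p_dominance"),
    ):
        if results.empty:
            continue
        sub = results[["chr", "pos", col]].copy()
        sub.columns = ["chrom", "position", "neglog10p"]
        sub["test"] = test
        rows.append(sub.dropna(subset=["neglog10p"]))
    if rows:
        long = pd.concat(rows, ignore_index=True)
        long = long.sort_values(
            by=["chrom", "position"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
    else:
        long = pd.DataFrame(columns=["chrom", "position", "neglog10p", "test"])
    long.to_csv(path, sep="\t", index=False)

    if plot_path is not None and not long.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
        for ax, test in zip(axes, ("additive", "dominance")):
            sub = long[long["test"] == test]
            ax.scatter(range(len(sub)), sub["neglog10p"], s=4)
            ax.set_ylabel(f"log10(1/p), {test}")
        axes[1].set_xlabel("SNP (genome order)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return long


def write_population(pop, out_dir: PathLike) -> dict:
    """Write a simulated population as the files the pipeline reads back.

    Returns the mapping of artifact name to path.  Ground truth goes to
    JSON (causal effects and realized decompositions; breeding values to a
    separate CSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.csv",
        "pedigree": out / "pedigree.csv",
        "snp_map": out / "snp_map.tsv",
        "truth": out / "truth.json",
        "breeding_values": out / "breeding_values.csv",
    }
    write_genotypes(pop.genotypes, paths["genotypes"])
    write_phenotypes(pop.phenotypes, paths["phenotypes"])
    write_pedigree(pop.pedigree, paths["pedigree"])
    write_snp_map(pop.snp_map, paths["snp_map"])
    truth = {
        "causal": [
            {
                "index": c.index,
                "snp": c.snp,
                "g": [c.g.g11, c.g.g12, c.g.g22],
                "alpha": c.alpha,
                "delta": c.delta,
                "p1": c.freqs.p1,
                "P11": c.freqs.P11,
                "P12": c.freqs.P12,
                "P22": c.freqs.P22,
            }
            for c in pop.truth.causal
        ],
        "founder_freq2": pop.truth.founder_freq2.tolist(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    pd.DataFrame(
        {
            "animal_id": pop.phenotypes.animal_id,
            "breeding_value": pop.truth.breeding_values,
        }
    ).to_csv(paths["breeding_values"], index=False)
    return {k: str(v) for k, v in paths.items()}
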