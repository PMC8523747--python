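"""Readers and writers for the pipeline's plain-text formats.

Conventions: TSV with a header row and ids in the first column; beta
matrices stored probes x samples (the array-world convention) but held in
memory samples x probes; BED 0-based half-open; manifest positions 1-based
(Illumina convention); JSON sidecars record parameters, package version,
seed and input checksums next to every written table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

import clonmeth
from clonmeth.preprocess import MethylationCohort

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_table",
    "write_table",
    "read_bed",
    "write_bed",
    "write_fasta",
    "read_term_to_genes",
    "write_term_to_genes",
    "read_cohort",
    "write_cohort",
    "write_sidecar",
    "sha256_of",
]


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    """Write a samples x probes beta frame as probes x samples TSV."""
    out = beta.T
    out.index.name = "probe"
    out.to_csv(path, sep="\t")


def read_beta_tsv(path) -> pd.DataFrame:
    """Read a probes x samples TSV into a samples x probes frame."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bed(bed: pd.DataFrame, path) -> None:
    bed[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )


def write_fasta(ids: Sequence[str], sequences: Sequence[str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(ids, sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_term_to_genes(term_to_genes: Mapping[str, Sequence[str]], path) -> None:
    rows = [(t, g) for t, genes in term_to_genes.items() for g in genes]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)


def read_term_to_genes(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {t: sorted(g["gene"].astype(str)) for t, g in df.groupby("term")}


def write_cohort(cohort: MethylationCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_beta_tsv(cohort.beta, outdir / "beta.tsv")
    cohort.samples.to_csv(outdir / "samples.tsv", sep="\t")
    if cohort.cell_fractions is not None:
        cohort.cell_fractions.to_csv(outdir / "cell_fractions.tsv", sep="\t")


def read_cohort(outdir) -> MethylationCohort:
    outdir = Path(outdir)
    beta = read_beta_tsv(outdir / "beta.tsv")
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0)
    frac_path = outdir / "cell_fractions.tsv"
    fractions = (
        pd.read_csv(frac_path, sep="\t", index_col=0) if frac_path.exists() else None
    )
    return MethylationCohort(beta.loc[samples.index], samples, fractions)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(path, parameters: Mapping, seed: int | None, inputs: Sequence = ()) -> None:
    """JSON provenance sidecar written next to a pipeline artifact."""
    sidecar = {
        "artifact": str(path),
        "version": clonmeth.__version__,
        "seed": seed,
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "input_checksums": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def _jsonable(v):
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    if isinstance(v, Mapping):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return str(v)
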