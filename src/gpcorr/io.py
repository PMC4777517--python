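"""File formats: GP-map tables, phenotype tables, and JSON metadata sidecars.

The on-disk map format is a two-column TSV (``genotype<TAB>phenotype``)
with a header line, optionally gzip-compressed (detected by a ``.gz``
suffix).  Genotype strings are stored verbatim; phenotype labels are free
text without tabs.  Every writer can drop a ``<path>.meta.json`` sidecar
recording the producing configuration, seeds, and a content hash, so
stochastic runs can be replayed bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .space import GenotypeSpace, GPMap, InvalidGenotypeError, PhenotypeTable

__all__ = [
    "read_gpmap",
    "write_gpmap",
    "read_phenotype_table",
    "content_hash",
    "write_sidecar",
    "read_sidecar",
    "MalformedTableError",
]


class MalformedTableError(ValueError):
    """A map or phenotype table on disk violates the format contract."""


def write_gpmap(gpmap: GPMap, path) -> None:
    """Write a complete map as ``genotype<TAB>phenotype`` TSV (gzip by suffix)."""
    gpmap.require_complete("serialisation to TSV")
    space = gpmap.space
    genotypes = [space.genotype(r) for r in range(space.n_genotypes)]
    phenotypes = [gpmap.labels[int(c)] for c in gpmap.codes]
    pd.DataFrame({"genotype": genotypes, "phenotype": phenotypes}).to_csv(
        path, sep="\t", index=False
    )


def read_gpmap(path, alphabet: str | None = None, del_label: str | None = None) -> GPMap:
    """Read a complete GP map from TSV, validating length/alphabet consistency.

    If ``alphabet`` is not given it is inferred as the sorted set of
    characters appearing in the genotypes.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (FileNotFoundError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise MalformedTableError(f"cannot read map table {path}: {e}") from e
    if list(df.columns) != ["genotype", "phenotype"]:
        raise MalformedTableError(
            f"expected header 'genotype<TAB>phenotype', got {list(df.columns)}"
        )
    if df.empty:
        raise MalformedTableError("map table is empty")
    genotypes = df["genotype"].tolist()
    L = len(genotypes[0])
    if alphabet is None:
        alphabet = "".join(sorted({c for g in genotypes for c in g}))
    space = GenotypeSpace(alphabet=alphabet, L=L)
    if len(df) != space.n_genotypes:
        raise MalformedTableError(
            f"table has {len(df)} rows but K^L = {space.n_genotypes}; map must be total"
        )
    assignment = dict(zip(genotypes, df["phenotype"].tolist()))
    if len(assignment) != len(df):
        raise MalformedTableError("duplicate genotype rows")
    try:
        return GPMap.from_assignment(space, assignment, del_label=del_label)
    except InvalidGenotypeError as e:
        raise MalformedTableError(str(e)) from e


def read_phenotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"phenotype": str})
    required = {"phenotype", "count", "frequency"}
    if not required.issubset(df.columns):
        raise MalformedTableError(f"phenotype table needs columns {sorted(required)}")
    return df


def content_hash(path) -> str:
    """SHA-256 of a file's bytes, prefixed with the algorithm name."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return "sha256:" + h.hexdigest()


def write_sidecar(out_path, payload: dict) -> Path:
    """Write ``<out_path>.meta.json`` describing how ``out_path`` was produced."""
    side = Path(str(out_path) + ".meta.json")
    payload = dict(payload)
    if Path(out_path).exists():
        payload["output_hash"] = content_hash(out_path)
    side.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return side


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
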