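"""Readers and writers for the pipeline's plain-text formats.

All tabular inputs are TSV: beta matrices and mutation/expression
matrices with the feature id in the first column, manifests and clinical
tables keyed by ``probe_id`` / ``sample_id``. Blacklists are one probe id
per line; gene sets are GMT (see :mod:`cimp.downstream`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_beta",
    "read_manifest",
    "read_clinical",
    "read_mutations",
    "read_maf",
    "read_normal_ref",
    "read_blacklist",
    "read_matrix",
    "write_json",
]

MANIFEST_COLUMNS = ("probe_id", "chr", "pos", "relation_to_island", "gene")
CGI_VOCABULARY = frozenset({"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"})


def read_beta(path) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta.index.name = "probe_id"
    vals = beta.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"beta-values outside [0, 1] in {path}")
    return beta


def read_matrix(path) -> pd.DataFrame:
    """Generic feature x sample TSV (mutations, expression, immune)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_manifest(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = set(MANIFEST_COLUMNS[:4]) - set(ann.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    bad = set(ann["relation_to_island"].dropna().unique()) - CGI_VOCABULARY
    if bad:
        raise ValueError(f"manifest relation_to_island outside vocabulary: {sorted(bad)}")
    if "gene" not in ann.columns:
        ann["gene"] = ""
    ann["gene"] = ann["gene"].fillna("")
    return ann.set_index("probe_id", drop=False)


def read_clinical(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if "sample_id" not in tab.columns:
        raise ValueError(f"clinical table {path} lacks a sample_id column")
    return tab.set_index("sample_id", drop=False)


def read_mutations(path) -> pd.DataFrame:
    """Binary gene x sample TSV; values coerced to {0,1}."""
    mut = pd.read_csv(path, sep="\t", index_col=0)
    vals = mut.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mutation matrix {path} must be binary")
    mut.index.name = "gene"
    return mut.astype(np.int8)


def read_maf(path) -> pd.DataFrame:
    """MAF to binary matrix: any non-silent variant of a gene in a sample
    sets the indicator to 1."""
    maf = pd.read_csv(path, sep="\t", comment="#")
    needed = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
    if not needed <= set(maf.columns):
        raise ValueError(f"MAF {path} lacks columns {sorted(needed - set(maf.columns))}")
    if "Variant_Classification" in maf.columns:
        maf = maf[maf["Variant_Classification"] != "Silent"]
    mat = pd.crosstab(maf["Hugo_Symbol"], maf["Tumor_Sample_Barcode"])
    mat.index.name = "gene"
    return (mat > 0).astype(np.int8)


def read_normal_ref(path) -> pd.Series:
    ref = pd.read_csv(path, sep="\t", index_col=0)
    return ref.iloc[:, 0].rename("normal_ref")


def read_blacklist(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
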