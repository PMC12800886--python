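"""Readers and writers for the pipeline's tabular artifacts.

The canonical on-disk dialect is TSV (tab-separated, UTF-8, '.'
decimal) for lowest-friction interoperability with amplicon tooling.
Networks are additionally exported as GraphML; metric reports as JSON
with full provenance (seed, optimizer options, binarization rule).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .networks import BipartiteNetwork, to_graph

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "read_effects_table",
    "write_effects_table",
    "write_edge_list",
    "write_graphml",
    "write_metrics_report",
    "read_metrics_report",
    "write_truth",
]

logger = logging.getLogger("grazenet")

TREATMENT_CLASSES = ("control", "grazing", "mucus")


def read_count_table(path, orientation: str = "samples_x_asvs") -> pd.DataFrame:
    """Read a TSV count table; returns samples x ASVs integers.

    ``orientation="asvs_x_samples"`` transposes a file whose rows are
    ASVs. Raises on duplicate ids and on negative or non-integer
    entries (naming the offending cell).
    """
    if orientation not in ("samples_x_asvs", "asvs_x_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "asvs_x_samples":
        df = df.T
    if df.index.duplicated().any():
        dups = list(df.index[df.index.duplicated()])
        raise ValueError(f"duplicate sample id(s): {dups}")
    if df.columns.duplicated().any():
        dups = list(df.columns[df.columns.duplicated()])
        raise ValueError(f"duplicate ASV id(s): {dups}")
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) \
        | (arr.astype(float) != np.floor(arr.astype(float)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid count at sample {df.index[i]!r}, ASV {df.columns[j]!r}: "
            f"{df.iat[i, j]!r} (counts must be non-negative integers)"
        )
    out = df.astype(np.int64)
    out.index.name = "sample_id"
    return out


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read sample metadata (sample_id, treatment_class, grazer, replicate).

    Validates treatment classes, the control/grazer exclusivity rule,
    and (when `counts` is given) coverage of every counted sample.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"grazer": "string"})
    required = {"sample_id", "treatment_class"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad = set(meta["treatment_class"]) - set(TREATMENT_CLASSES)
    if bad:
        raise ValueError(f"unknown treatment_class value(s): {sorted(bad)}")
    grazer = meta.get("grazer", pd.Series(pd.NA, index=meta.index, dtype="string"))
    has_grazer = grazer.notna() & (grazer.astype(str).str.strip() != "")
    is_ctrl = meta["treatment_class"] == "control"
    if (is_ctrl & has_grazer).any():
        raise ValueError(
            f"control sample(s) with a grazer label: {list(meta.index[is_ctrl & has_grazer])}"
        )
    if (~is_ctrl & ~has_grazer).any():
        raise ValueError(
            f"grazing/mucus sample(s) without a grazer: {list(meta.index[~is_ctrl & ~has_grazer])}"
        )
    if counts is not None:
        uncovered = [s for s in counts.index if s not in meta.index]
        if uncovered:
            raise ValueError(f"metadata missing counted sample(s): {uncovered}")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read an ASV taxonomy table (asv_id plus ranked lineage columns)."""
    tax = pd.read_csv(path, sep="\t")
    if "asv_id" not in tax.columns:
        raise ValueError("taxonomy missing 'asv_id' column")
    tax = tax.set_index("asv_id")
    if counts is not None:
        unknown = [a for a in tax.index if a not in counts.columns]
        if unknown:
            raise ValueError(f"taxonomy lists unknown ASV id(s): {unknown}")
    return tax


def write_effects_table(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, sep="\t", index=False)


def read_effects_table(path) -> pd.DataFrame:
    eff = pd.read_csv(path, sep="\t")
    eff["significant"] = eff["significant"].astype(bool)
    return eff


def write_edge_list(network: BipartiteNetwork, path) -> None:
    """TSV edge list: source, target, weight (|DI|), sign, mode, family.

    Non-negative weights with a separate sign column, as assumed by
    downstream network viewers. Empty networks produce a header-only
    file plus a warning log entry.
    """
    rows = []
    arr = network.weights.to_numpy()
    for i, j in zip(*np.nonzero(arr > 0)):
        asv = network.asv_ids[j]
        fam = ""
        if network.family is not None:
            v = network.family.get(asv)
            fam = "" if pd.isna(v) else str(v)
        rows.append((network.grazers[i], asv, arr[i, j], network.sign, network.mode, fam))
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "mode", "family"])
    if df.empty:
        logger.warning("writing empty network (%s, %s) to %s",
                       network.mode, network.sign, path)
    df.to_csv(path, sep="\t", index=False)


def write_graphml(network: BipartiteNetwork, path) -> None:
    nx.write_graphml(to_graph(network), path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_metrics_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
        fh.write("\n")


def read_metrics_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_truth(truth, path_prefix) -> None:
    """Write ground-truth effect matrices as TSV (one file per mode)."""
    prefix = Path(path_prefix)
    truth.delta_ti.to_csv(prefix.with_suffix(".trophic.tsv"), sep="\t",
                          index_label="grazer")
    truth.delta_nti.to_csv(prefix.with_suffix(".non_trophic.tsv"), sep="\t",
                           index_label="grazer")
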