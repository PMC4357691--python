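"""Readers and writers for the package's plain-text formats.

Expression matrices are tab-separated: header row of sample IDs, first
column of gene IDs, genes as rows.  Gold-standard networks follow the
DREAM-challenge edge-list dialect: two or three tab-separated columns
(regulator, target, optional 0/1 flag), where an explicit 0 marks a known
non-edge.  Inferred networks are written as scored edge lists with a
self-describing comment header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ExpressionMatrix",
    "GoldStandard",
    "read_expression",
    "write_expression",
    "read_gold_standard",
    "write_gold_standard",
    "write_network",
    "read_network",
    "write_metrics",
    "write_roc_points",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × samples expression matrix with named axes."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise InputError(f"duplicate gene IDs: {dupes}")
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise InputError(f"duplicate sample IDs: {dupes}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise InputError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite value at gene {self.genes[g]!r}, sample {self.samples[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))


@dataclass(frozen=True)
class GoldStandard:
    """Positive edges plus explicitly listed known non-edges (both as
    unordered pairs); any pair not listed is treated as negative."""

    positives: frozenset
    known_negatives: frozenset

    def __post_init__(self) -> None:
        overlap = self.positives & self.known_negatives
        if overlap:
            raise InputError(f"pairs listed as both edge and non-edge: {sorted(map(sorted, overlap))}")

    @property
    def genes(self) -> set:
        out = set()
        for pair in self.positives | self.known_negatives:
            out |= set(pair)
        return out


def read_expression(path, *, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Default orientation is genes-as-rows; pass ``transpose=True`` for
    samples-as-rows files.  Missing or non-numeric cells are reported with
    their gene and sample IDs.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError
                values[i, j] = float(cell)
                if not np.isfinite(values[i, j]):
                    raise ValueError
            except (TypeError, ValueError):
                raise InputError(
                    f"{path}: missing or non-numeric value {cell!r} at "
                    f"gene {genes[i]!r}, sample {samples[j]!r}"
                ) from None
    return ExpressionMatrix(tuple(genes), tuple(samples), values)


def write_expression(path, expr: ExpressionMatrix) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", float_format="%.15g", index_label="gene")


def read_gold_standard(path) -> GoldStandard:
    """Read a DREAM-style edge list (2 or 3 tab-separated columns)."""
    positives: set = set()
    negatives: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise InputError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise InputError(f"{path}:{lineno}: empty gene name")
            if a == b:
                raise InputError(f"{path}:{lineno}: self-edge {a!r}")
            flag = fields[2].strip() if len(fields) == 3 else "1"
            if flag not in ("0", "1"):
                raise InputError(f"{path}:{lineno}: edge flag must be 0 or 1, got {flag!r}")
            pair = frozenset((a, b))
            target = positives if flag == "1" else negatives
            other = negatives if flag == "1" else positives
            if pair in other:
                raise InputError(
                    f"{path}:{lineno}: pair ({a}, {b}) listed as both edge and non-edge"
                )
            target.add(pair)
    return GoldStandard(frozenset(positives), frozenset(negatives))


def write_gold_standard(path, positives, known_negatives=()) -> None:
    rows = sorted((tuple(sorted(p)), 1) for p in positives)
    rows += sorted((tuple(sorted(p)), 0) for p in known_negatives)
    with open(path, "w") as fh:
        for (a, b), flag in rows:
            fh.write(f"{a}\t{b}\t{flag}\n")


def write_network(path, net, *, config=None) -> None:
    """Write a scored edge list TSV with a self-describing comment header.

    One row per gene pair ever scored; canonical (sorted) gene order per
    row; ``present`` records whether the edge survived inference and
    ``decision_order`` the conditioning order at which it was decided.
    """
    from . import __version__

    lines = [f"# cmi2ni v{__version__}"]
    if config is not None:
        lines.append(
            "# theta=%g measure=%s aggregation=%s max_order=%s"
            % (config.theta, config.measure, config.aggregation,
               "unlimited" if config.max_order is None else config.max_order)
        )
    lines.append(f"# final_order={net.final_order}")
    lines.append("gene_a\tgene_b\tscore\tpresent\tdecision_order")
    for pair in sorted(net.edge_scores, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        lines.append(
            f"{a}\t{b}\t{net.edge_scores[pair]:.15g}\t"
            f"{int(net.has_edge(a, b))}\t{net.decision_order[pair]}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_network(path):
    """Read a scored edge list written by :func:`write_network` back into a
    :class:`~cmi2ni.inference.Network`."""
    from .inference import Network

    final_order = 0
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "final_order=" in line:
                    final_order = int(line.split("final_order=")[1].split()[0])
                continue
            fields = line.split("\t")
            if fields[0] == "gene_a":
                continue
            if len(fields) != 5:
                raise InputError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            rows.append((fields[0], fields[1], float(fields[2]), bool(int(fields[3])), int(fields[4])))
    genes = sorted({g for r in rows for g in r[:2]})
    edges = {frozenset((a, b)) for a, b, _, present, _ in rows if present}
    scores = {frozenset((a, b)): s for a, b, s, _, _ in rows}
    orders = {frozenset((a, b)): o for a, b, _, _, o in rows}
    return Network(tuple(genes), edges, scores, orders, final_order)


def write_metrics(path_tsv, path_json, metric_set) -> None:
    """Write a metric report as TSV and JSON (undefined metrics are written
    as 'NA' / null, never silently zero)."""
    d = metric_set.as_dict()
    with open(path_tsv, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in d.items():
            fh.write(f"{k}\t{'NA' if v is None else '%.6g' % v}\n")
    with open(path_json, "w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")


def write_roc_points(path, points) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.15g}\t{tpr:.15g}\n")
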