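"""Readers and writers for the pipeline's tab-separated formats.

All files are UTF-8 with LF newlines.  Formats:

* expression matrix — header row of sample ids, first column probe ids,
  remaining cells log2 intensities (``input_scale="linear"`` applies
  log2(x + 1) on load);
* sample metadata — columns sample_id, condition, platform;
* probe annotation — columns probe_id, gene_symbol, control_class, qc_gene;
* target pairs — columns mirna_id, gene_symbol, evidence, source;
* gene sets — GMT with an optional sign suffix per member: ``SYM:+1`` /
  ``SYM:-1`` carry the direction consistent with set activation, bare
  ``SYM`` is unsigned;
* gene-level DE calls — columns gene_symbol, direction.

Readers fail loudly on structural violations, naming the offending line;
nothing is silently coerced.  Gene symbols are matched case-sensitively
throughout the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    DEGSet,
    EVIDENCE_CLASSES,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    QpcrTable,
    SampleTable,
    TargetPairTable,
    ValidationError,
)


class ParseError(ValidationError):
    """A malformed input file; the message cites the offending line."""


def read_expression_matrix(path, platform: str, input_scale: str = "log2") -> ExpressionMatrix:
    """Read a probes-by-samples expression matrix.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file; first header field is ignored (probe-id column
        label), remaining header fields are sample ids.
    platform : {"mRNA", "miRNA"}
    input_scale : {"log2", "linear"}
        With "linear" the values are transformed by log2(x + 1) on load.
    """
    if input_scale not in ("log2", "linear"):
        raise ValidationError(f"input_scale must be log2|linear, got {input_scale!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        if not sample_ids:
            raise ParseError(f"{path}: header has no sample columns")
        seen_samples = set()
        for s in sample_ids:
            if s in seen_samples:
                raise ParseError(f"{path}: duplicate sample id {s!r} in header")
            seen_samples.add(s)
        ncol = len(sample_ids)
        probe_ids: list[str] = []
        seen_probes: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol + 1} fields, got {len(fields)}"
                )
            probe = fields[0]
            if probe in seen_probes:
                raise ParseError(f"{path}: line {lineno}: duplicate probe id {probe!r}")
            seen_probes.add(probe)
            try:
                values = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
            if not all(np.isfinite(values)):
                raise ParseError(f"{path}: line {lineno}: non-finite value")
            probe_ids.append(probe)
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    mat = np.asarray(rows, dtype=float)
    if input_scale == "linear":
        if (mat < 0).any():
            raise ParseError(f"{path}: negative intensity under input_scale=linear")
        mat = np.log2(mat + 1.0)
    df = pd.DataFrame(mat, index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(platform, df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, row in matrix.data.iterrows():
            fh.write(probe + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ProbeAnnotation(df)


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_target_pairs(path) -> TargetPairTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("mirna_id", "gene_symbol", "evidence", "source") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = ~df["evidence"].isin(EVIDENCE_CLASSES)
    if bad.any():
        lineno = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ParseError(
            f"{path}: line {lineno}: unknown evidence {df.loc[bad, 'evidence'].iloc[0]!r}; "
            f"accepted tokens: {', '.join(EVIDENCE_CLASSES)}"
        )
    dup = df.duplicated(subset=["mirna_id", "gene_symbol"])
    if dup.any():
        lineno = int(np.flatnonzero(dup)[0]) + 2
        raise ParseError(f"{path}: line {lineno}: duplicated (mirna, gene) pair")
    return TargetPairTable(df)


def write_target_pairs(table: TargetPairTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file in the signed-member dialect (see module docstring)."""
    sets: dict[str, dict[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description, >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members: dict[str, int] = {}
            for token in fields[2:]:
                if not token:
                    continue
                sign = 0
                sym = token
                if token.endswith(":+1"):
                    sym, sign = token[:-3], 1
                elif token.endswith(":-1"):
                    sym, sign = token[:-3], -1
                if not sym:
                    raise ParseError(f"{path}: line {lineno}: empty member symbol")
                if sym in members:
                    raise ParseError(
                        f"{path}: line {lineno}: duplicate member {sym!r} in set {name!r}"
                    )
                members[sym] = sign
            sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    suffix = {1: ":+1", -1: ":-1", 0: ""}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection:
            tokens = [f"{g}{suffix[s]}" for g, s in members.items()]
            fh.write("\t".join([name, ""] + tokens) + "\n")


def read_degset(path, contrast_id: str | None = None) -> DEGSet:
    """Read gene-level DE calls (columns gene_symbol, direction)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene_symbol", "direction") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    dup = df["gene_symbol"].duplicated()
    if dup.any():
        lineno = int(np.flatnonzero(dup)[0]) + 2
        raise ParseError(f"{path}: line {lineno}: duplicate gene symbol")
    directions = dict(zip(df["gene_symbol"], df["direction"]))
    return DEGSet(contrast_id or str(path), directions)


def write_degset(degset: DEGSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_symbol\tdirection\n")
        for gene in sorted(degset.directions):
            fh.write(f"{gene}\t{degset.directions[gene]}\n")


def read_qpcr_table(path, reference_gene: str = "GAPDH") -> QpcrTable:
    df = pd.read_csv(path, sep="\t")
    return QpcrTable(df, reference_gene=reference_gene)


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list (e.g. an enrichment universe)."""
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    seen: set[str] = set()
    out = []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out
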