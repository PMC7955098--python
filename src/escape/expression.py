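"""Gene-expression quantification: RPKM, expressed/differential/dependent sets.

Expression is summarized per gene and condition as RPKM (reads per
kilobase of exonic length per million mapped exonic reads). Genes with
RPKM > 1 in either compared condition form the expressed universe; a
strict fold-change rule (default > 2.5, with a 0.1-RPKM pseudocount)
defines up/down-regulated genes, and a second fold rule against a
knockout condition defines co-factor-dependent induced genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel

__all__ = [
    "ExpressionTable",
    "rpkm",
    "differential_genes",
    "dependent_genes",
]

EXPRESSED_RPKM = 1.0
RPKM_PSEUDOCOUNT = 0.1


def rpkm(count: float, exonic_length_bp: int, total_exonic_reads: int) -> float:
    """count / (exonic kb) / (million mapped exonic reads)."""
    if exonic_length_bp < 1:
        raise ValueError("exonic length must be >= 1")
    if total_exonic_reads < 1:
        raise ValueError("total exonic reads must be >= 1")
    return count / (exonic_length_bp / 1e3) / (total_exonic_reads / 1e6)


@dataclass
class ExpressionTable:
    """Exonic read counts per gene x condition with derived RPKM.

    ``counts`` is a genes-by-conditions DataFrame; ``lengths`` the exonic
    length per gene (bp). RPKM for a condition uses that condition's total
    mapped exonic reads as the library size: by default the column sum,
    overridden by ``library_sizes`` when the table covers only a gene
    panel inside a larger library.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs an exonic length")
        if self.library_sizes is not None:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ValueError("every condition needs a library size")

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)

    def rpkm(self, condition: str | None = None) -> pd.DataFrame | pd.Series:
        totals = (self.counts.sum(axis=0) if self.library_sizes is None
                  else self.library_sizes)
        if (totals < 1).any():
            raise ValueError("each condition needs >= 1 exonic read")
        kb = self.lengths / 1e3
        table = self.counts.div(kb, axis=0).div(totals / 1e6, axis=1)
        return table if condition is None else table[condition]

    def expressed(self, condition: str) -> pd.Index:
        r = self.rpkm(condition)
        return r.index[r > EXPRESSED_RPKM]

    def to_tsv(self, path: str) -> None:
        out = self.counts.copy()
        out.insert(0, "exonic_length", self.lengths)
        with open(path, "w") as fh:
            if self.library_sizes is not None:
                libs = ";".join(f"{c}={int(v)}"
                                for c, v in self.library_sizes.items())
                fh.write(f"#library_sizes\t{libs}\n")
            out.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionTable":
        with open(path) as fh:
            first = fh.readline()
            libs = None
            if first.startswith("#library_sizes"):
                pairs = first.rstrip("\n").split("\t")[1].split(";")
                libs = pd.Series({k: float(v) for k, v in
                                  (p.split("=") for p in pairs)})
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="gene_id")
        lengths = df.pop("exonic_length")
        return cls(counts=df, lengths=lengths, library_sizes=libs)

    @classmethod
    def from_counts(
        cls,
        genes: Sequence[GeneModel],
        counts: Mapping[str, np.ndarray],
        library_sizes: Mapping[str, float] | None = None,
    ) -> "ExpressionTable":
        idx = pd.Index([g.gene_id for g in genes], name="gene_id")
        df = pd.DataFrame({c: np.asarray(v) for c, v in counts.items()}, index=idx)
        lengths = pd.Series([g.exonic_length for g in genes], index=idx)
        libs = pd.Series(library_sizes) if library_sizes is not None else None
        return cls(counts=df, lengths=lengths, library_sizes=libs)


def differential_genes(
    rpkm_a: pd.Series,
    rpkm_b: pd.Series,
    fold: float = 2.5,
    pseudocount: float = RPKM_PSEUDOCOUNT,
) -> tuple[pd.Index, pd.Index]:
    """(up, down) gene sets between conditions A and B.

    The universe is genes expressed (RPKM > 1) in A or B; a gene is up
    when (RPKM_B + pc) / (RPKM_A + pc) strictly exceeds ``fold``, and
    down symmetrically.
    """
    a, b = rpkm_a.align(rpkm_b, join="inner")
    universe = (a > EXPRESSED_RPKM) | (b > EXPRESSED_RPKM)
    a, b = a[universe], b[universe]
    ratio = (b + pseudocount) / (a + pseudocount)
    return a.index[ratio > fold], a.index[ratio < 1 / fold]


def dependent_genes(
    up_genes: Iterable[str],
    rpkm_control: pd.Series,
    rpkm_ko: pd.Series,
    fold: float = 2.5,
    pseudocount: float = RPKM_PSEUDOCOUNT,
) -> pd.Index:
    """Up-regulated genes whose induced level collapses in the knockout.

    A gene is dependent when its control induced level exceeds the
    knockout induced level by strictly more than ``fold``.
    """
    idx = pd.Index(up_genes)
    c = rpkm_control.reindex(idx)
    k = rpkm_ko.reindex(idx)
    ratio = (c + pseudocount) / (k + pseudocount)
    return idx[ratio > fold]
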