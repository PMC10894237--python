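"""Readers and writers for the pipeline's plain-text formats.

TSV tables go through pandas; BED is 0-based half-open; .rnk is the
two-column gene/score dialect; GMT is name TAB description TAB members.
"""

from __future__ import annotations

import pandas as pd

from .gsea_lite import GeneSet

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_counts_matrix(path) -> pd.DataFrame:
    """Counts TSV keyed by a first id column (regions or guides x samples)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_spike_totals(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]].rename("spike_total")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "value"]
    return df


def read_rnk(path) -> pd.Series:
    """Ranked list: gene TAB score, no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "score"])
    s = df.set_index("gene")["score"]
    if s.index.has_duplicates:
        raise ValueError("duplicate gene ids in .rnk file")
    return s.sort_values(ascending=False, kind="mergesort")


def write_rnk(ranked: pd.Series, path) -> None:
    ranked.to_csv(path, sep="\t", header=False)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append(GeneSet(name=fields[0], description=fields[1],
                                members=frozenset(f for f in fields[2:] if f)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")
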