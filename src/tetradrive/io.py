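"""Tabular writers: single-header TSV tables and JSON-lines spore records."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genetics import Ascus, CrossSpec
from .simulate import AscusCountTable


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_count_table(table: AscusCountTable, path: str | Path) -> None:
    write_tsv(table.to_frame(), path)


def write_spore_jsonl(
    cross: CrossSpec, asci: Iterable[Ascus], path: str | Path
) -> None:
    """One JSON record per spore: ascus index, nuclei genotypes and flags."""
    with open(path, "w") as fh:
        for ascus_index, ascus in enumerate(asci):
            for spore_index, spore in enumerate(ascus.spores):
                record = {
                    "ascus": ascus_index,
                    "spore": spore_index,
                    "viable": spore.viable,
                    "pigmented": spore.pigmented,
                    "nuclei": [dict(n.alleles) for n in spore.nuclei],
                    "sds_pattern": ascus.sds_pattern,
                }
                fh.write(json.dumps(record, sort_keys=True) + "\n")
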