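"""Guide-barcode library handling.

A pooled screen library maps guide ids to gene symbols and 20-nt spacer
sequences.  What in situ sequencing actually reads out is the *reverse
complement* of the spacer (the detect sequence), so the library carries
both, and the dictionary used for matching is built from detect sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BarcodeLibrary:
    """Guide ↔ gene table with spacers and their detect sequences.

    ``entries`` columns: guide_id, gene, spacer, detect_seq, ambiguous.
    ``ambiguous`` flags entries whose spacer is shared with another entry;
    matches to such a group are treated as ambiguous downstream.
    """

    entries: pd.DataFrame
    is_scrambled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("no entries")
        lengths = self.entries["spacer"].str.len().unique()
        if len(lengths) != 1:
            raise ValueError("all spacers must have the same length")
        if self.entries["guide_id"].duplicated().any():
            dups = self.entries.loc[
                self.entries["guide_id"].duplicated(), "guide_id"
            ].tolist()
            raise ValueError(f"duplicate guide_id: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def spacer_length(self) -> int:
        return len(self.entries["spacer"].iloc[0])

    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())


def _validate_and_build(df: pd.DataFrame) -> pd.DataFrame:
    keep = []
    for i, row in df.iterrows():
        spacer = str(row["spacer"]).upper()
        if not set(spacer) <= DNA_ALPHABET:
            logger.warning(
                "rejecting entry %s: non-ACGT character in spacer %r",
                row["guide_id"],
                spacer,
            )
            continue
        keep.append(
            {
                "guide_id": str(row["guide_id"]),
                "gene": str(row["gene"]),
                "spacer": spacer,
                "detect_seq": reverse_complement(spacer),
            }
        )
    out = pd.DataFrame(keep, columns=["guide_id", "gene", "spacer", "detect_seq"])
    if len(out):
        dup_mask = out["spacer"].duplicated(keep=False)
        if dup_mask.any():
            logger.warning(
                "%d entries share spacers with another entry; flagged ambiguous",
                int(dup_mask.sum()),
            )
        out["ambiguous"] = dup_mask
    return out


def load_library(table_path, spacer_column: str = "spacer") -> BarcodeLibrary:
    """Load a guide library from a CSV/TSV with guide_id, gene, spacer columns.

    Detect sequences are computed as reverse complements.  Entries with
    non-ACGT spacers are dropped with a logged warning; duplicated spacers
    are kept but flagged ambiguous; duplicated guide ids are an error.
    """
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(table_path, sep=sep)
    missing = {"guide_id", "gene", spacer_column} - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    if spacer_column != "spacer":
        df = df.rename(columns={spacer_column: "spacer"})
    entries = _validate_and_build(df)
    if len(entries) == 0:
        raise ValueError("no entries")
    return BarcodeLibrary(entries=entries)


def library_from_records(records: list[dict]) -> BarcodeLibrary:
    """Build a library from in-memory records with guide_id, gene, spacer."""
    entries = _validate_and_build(pd.DataFrame(records))
    if len(entries) == 0:
        raise ValueError("no entries")
    return BarcodeLibrary(entries=entries)


def scramble_library(
    lib: BarcodeLibrary, seed: int, per_sequence: bool = True
) -> BarcodeLibrary:
    """Permute detect sequences to build a matched negative-control dictionary.

    Each detect sequence is replaced by a seeded random permutation of its
    own characters, preserving the per-sequence base composition (the
    stricter reading of an equal-base-distribution scramble).  With
    ``per_sequence=False`` the characters are permuted across the whole
    library instead, preserving only the global composition.
    """
    rng = np.random.default_rng(seed)
    entries = lib.entries.copy()
    if per_sequence:
        scrambled = [
            "".join(rng.permutation(list(s))) for s in entries["detect_seq"]
        ]
    else:
        chars = np.array(list("".join(entries["detect_seq"])))
        chars = rng.permutation(chars)
        L = lib.spacer_length
        scrambled = [
            "".join(chars[i * L : (i + 1) * L]) for i in range(len(entries))
        ]
    entries["detect_seq"] = scrambled
    entries["spacer"] = [reverse_complement(s) for s in scrambled]
    entries["ambiguous"] = entries["spacer"].duplicated(keep=False)
    return BarcodeLibrary(
        entries=entries,
        is_scrambled=True,
        meta={**lib.meta, "scramble_seed": seed, "scramble_per_sequence": per_sequence},
    )
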