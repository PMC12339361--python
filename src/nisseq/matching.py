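"""Barcode dictionary matching with single-mismatch error correction.

Called spot sequences are assigned to the dictionary of known detect
sequences (reverse-complemented spacers) allowing zero or one mismatch and
no ambiguities.  An exact hit beats a distance-1 hit (distance-0 priority);
two or more hits within the same distance tier are ambiguous.  N counts as
a mismatch at its position.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class MatchResult:
    spot_id: int | None
    status: str  # exact | corrected | ambiguous | unmatched
    guide_id: str | None = None
    gene: str | None = None
    hamming_distance: int | None = None

    @property
    def matched(self) -> bool:
        return self.status in ("exact", "corrected")


class BarcodeIndex:
    """Hash index over detect-sequence prefixes supporting Hamming-≤1 lookup.

    Queries enumerate the 3·L single-substitution variants against the
    exact hash, giving O(L) lookups independent of library size.  Prefix
    collisions (two guides sharing a prefix at the chosen read length) and
    entries flagged ambiguous in the library form intrinsically ambiguous
    groups: any hit on them is reported ambiguous.
    """

    def __init__(self, lib, read_length: int):
        if read_length < 1:
            raise ValueError("read_length must be >= 1")
        if read_length > lib.spacer_length:
            raise ValueError(
                f"read_length {read_length} exceeds spacer length {lib.spacer_length}"
            )
        self.read_length = read_length
        self.exact: dict[str, list[int]] = {}
        self.guide_id = lib.entries["guide_id"].tolist()
        self.gene = lib.entries["gene"].tolist()
        flagged = lib.entries["ambiguous"].tolist()
        for i, seq in enumerate(lib.entries["detect_seq"]):
            self.exact.setdefault(seq[:read_length], []).append(i)
        # a prefix key is ambiguous if shared, or if any member was flagged
        self.ambiguous_keys = {
            k
            for k, idxs in self.exact.items()
            if len(idxs) > 1 or any(flagged[i] for i in idxs)
        }

    @property
    def n_collisions(self) -> int:
        return sum(
            1 for k, idxs in self.exact.items() if len(idxs) > 1
        )


def build_index(lib, read_length: int) -> BarcodeIndex:
    """Index detect-sequence prefixes of ``read_length`` bases for matching."""
    return BarcodeIndex(lib, read_length)


def match_sequence(
    seq: str, index: BarcodeIndex, spot_id: int | None = None
) -> MatchResult:
    """Match one called sequence against the dictionary (≤1 mismatch)."""
    L = index.read_length
    if len(seq) != L:
        raise ValueError(f"sequence length {len(seq)} != read length {L}")
    hit = index.exact.get(seq)
    if hit is not None:
        if seq in index.ambiguous_keys:
            return MatchResult(spot_id, "ambiguous", hamming_distance=0)
        i = hit[0]
        return MatchResult(
            spot_id, "exact", index.guide_id[i], index.gene[i], 0
        )
    # Hamming-1 neighborhood: one substitution per position.  Variants still
    # containing an N can never hit the ACGT dictionary, so N positions are
    # handled naturally (a read with ≥2 Ns cannot be corrected).
    keys: set[str] = set()
    for i in range(L):
        orig = seq[i]
        for b in "ACGT":
            if b == orig:
                continue
            variant = seq[:i] + b + seq[i + 1 :]
            if variant in index.exact:
                keys.add(variant)
    if not keys:
        return MatchResult(spot_id, "unmatched")
    if len(keys) > 1 or any(k in index.ambiguous_keys for k in keys):
        return MatchResult(spot_id, "ambiguous", hamming_distance=1)
    key = keys.pop()
    i = index.exact[key][0]
    return MatchResult(
        spot_id, "corrected", index.guide_id[i], index.gene[i], 1
    )


def match_profiles(profiles, index: BarcodeIndex) -> list[MatchResult]:
    """Match every called spot profile against the dictionary."""
    return [match_sequence(p.sequence, index, p.spot_id) for p in profiles]
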