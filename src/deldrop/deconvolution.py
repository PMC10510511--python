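"""Hit-bead tag sequencing, error-tolerant decoding, k classes, dose tiering.

Each sorted hit bead contributes one sequencing read of its concatenated
DNA tag.  Reads are decoded cycle segment by cycle segment: exact match,
else the unique tag within Hamming distance 1 (tag sets guarantee pairwise
distance >= 3, so distance-1 correction is unambiguous), else the read is
discarded with a reason.  One read corresponds to one bead, and the bead
is the replicate unit: a member's k class is its decoded bead count, and a
building block's cumulative k sums member k over all members that contain
it.

Comparing cumulative k between a high-UV (high-dose) and a low-UV screen
tiers every building block: enrichment at both doses marks a
high-priority hit series; enrichment only at the high dose marks a
dose-limited (likely weaker) series; counts at or below the noise level
are indistinguishable from sampling noise.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library import TAG_ALPHABET, LibraryCatalog
from .sorter import SortResult

DEFAULT_MIN_K = 4  # "large point" replicate class: clearly enriched
DEFAULT_NOISE_K = 3  # "small point" replicate class: bordering on noise

TIERS = ("high_priority", "dose_limited", "noise", "unobserved")


@dataclass(frozen=True)
class TagRead:
    read_id: str
    sequence: str
    quality: str | None = None


def reads_from_hits(
    sort: SortResult,
    catalog: LibraryCatalog,
    error_rate: float = 0.005,
    seed: int = 0,
) -> list[TagRead]:
    """One simulated tag read per sorted hit bead.

    Each read is the bead's concatenated member tag with i.i.d. per-base
    substitutions at ``error_rate``.
    """
    if not (0 <= error_rate < 0.2):
        raise ValueError("error_rate must lie in [0, 0.2)")
    rng = np.random.default_rng(seed)
    tags = catalog.tags.to_numpy()
    reads = []
    alphabet = np.frombuffer(TAG_ALPHABET.encode(), dtype=np.uint8)
    lookup = np.zeros(256, dtype=np.uint8)
    lookup[alphabet] = np.arange(4)
    for i, member in enumerate(sort.hit_bead_member):
        seq = np.frombuffer(tags[member].encode(), dtype=np.uint8).copy()
        if error_rate > 0:
            mask = rng.random(seq.size) < error_rate
            if mask.any():
                shift = rng.integers(1, 4, int(mask.sum()))
                seq[mask] = alphabet[(lookup[seq[mask]] + shift) % 4]
        reads.append(TagRead(read_id=f"hitbead_{i + 1:06d}", sequence=seq.tobytes().decode()))
    return reads


def write_fastq(reads: list[TagRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        qual = r.quality or "I" * len(r.sequence)
        rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in qual]
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[TagRead]:
    return [
        TagRead(
            read_id=rec.id,
            sequence=str(rec.seq),
            quality="".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(path, "fastq")
    ]


class _CycleDecoder:
    """Exact + Hamming-1 lookup for one cycle's tag set."""

    def __init__(self, tags: pd.Series, cycle: int):
        self.length = len(tags.iloc[0])
        self.exact: dict[str, int] = {}
        for idx, tag in enumerate(tags):
            if tag in self.exact:
                raise ValueError(f"cycle {cycle}: ambiguous duplicate tag {tag!r}")
            self.exact[tag] = idx
        # pairwise distance >= 3 makes distance-1 neighbourhoods disjoint
        for a in self.exact:
            for b in self.exact:
                if a < b and sum(x != y for x, y in zip(a, b)) < 3:
                    raise ValueError(
                        f"cycle {cycle}: tags {a!r}/{b!r} are within Hamming distance 2; "
                        "1-error correction would be ambiguous"
                    )

    def decode(self, segment: str) -> int | None:
        hit = self.exact.get(segment)
        if hit is not None:
            return hit
        if segment.count("N") > 1:
            return None
        found = None
        for i in range(self.length):
            prefix, suffix = segment[:i], segment[i + 1 :]
            for base in TAG_ALPHABET:
                if base == segment[i]:
                    continue
                cand = self.exact.get(prefix + base + suffix)
                if cand is not None:
                    if found is not None and cand != found:
                        return None  # cannot happen at distance >= 3; guard anyway
                    found = cand
        return found


@dataclass
class DecodeResult:
    """Per-member decoded bead counts plus discard accounting."""

    counts: pd.Series  # index: member position, value: bead count
    n_reads: int
    discards: Counter

    @property
    def n_decoded(self) -> int:
        return int(self.counts.sum())


def decode_reads(reads: list[TagRead], catalog: LibraryCatalog) -> DecodeResult:
    """Decode tag reads to library members.

    Policy per cycle segment: exact match, else unique match within
    Hamming distance 1 (a single N counts as one mismatch), else discard.
    Segments with more than one N are discarded as ambiguous.  Reads of
    the wrong length are discarded.
    """
    aa_dec = _CycleDecoder(catalog.aa["tag"], cycle=1)
    ca_dec = _CycleDecoder(catalog.ca["tag"], cycle=2)
    expected_len = aa_dec.length + ca_dec.length
    counts: Counter = Counter()
    discards: Counter = Counter()
    for read in reads:
        seq = read.sequence.upper()
        if len(seq) != expected_len:
            discards["bad_length"] += 1
            continue
        aa_seg, ca_seg = seq[: aa_dec.length], seq[aa_dec.length :]
        if aa_seg.count("N") > 1 or ca_seg.count("N") > 1:
            discards["ambiguous"] += 1
            continue
        aa_idx = aa_dec.decode(aa_seg)
        if aa_idx is None:
            discards["aa_no_match"] += 1
            continue
        ca_idx = ca_dec.decode(ca_seg)
        if ca_idx is None:
            discards["ca_no_match"] += 1
            continue
        counts[aa_idx * catalog.ca_count + ca_idx] += 1
    series = pd.Series(dict(counts), dtype=int).sort_index() if counts else pd.Series(dtype=int)
    return DecodeResult(counts=series, n_reads=len(reads), discards=discards)


@dataclass
class KClassTable:
    """Replicate (k class) accounting for one screen.

    ``members``: member_id, aa_id, ca_id, k, replicate_supported (k >= 2).
    ``bb``: bb_id, cycle, cumulative_k (sum of member k over members
    containing the building block).
    """

    members: pd.DataFrame
    bb: pd.DataFrame
    screen_label: str
    n_catalog_members: int

    @property
    def total_k(self) -> int:
        return int(self.members["k"].sum())

    def cumulative_k(self, bb_id: str) -> int:
        row = self.bb.loc[self.bb["bb_id"] == bb_id, "cumulative_k"]
        return int(row.iloc[0]) if len(row) else 0

    def write(self, prefix) -> None:
        self.members.to_csv(f"{prefix}.members.tsv", sep="\t", index=False)
        self.bb.to_csv(f"{prefix}.bb.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix, screen_label: str, n_catalog_members: int) -> "KClassTable":
        return cls(
            members=pd.read_csv(f"{prefix}.members.tsv", sep="\t"),
            bb=pd.read_csv(f"{prefix}.bb.tsv", sep="\t"),
            screen_label=screen_label,
            n_catalog_members=n_catalog_members,
        )


def k_class_table(decoded: DecodeResult, catalog: LibraryCatalog, screen_label: str) -> KClassTable:
    """Build per-member k and per-building-block cumulative k for one screen."""
    pos = decoded.counts.index.to_numpy(dtype=int)
    if len(pos) and (pos.min() < 0 or pos.max() >= catalog.n_members):
        raise ValueError("decoded counts reference members outside the catalog")
    k = decoded.counts.to_numpy(dtype=int)
    info = catalog.members.iloc[pos]
    members = pd.DataFrame(
        {
            "member_id": info["member_id"].to_numpy(),
            "aa_id": info["aa_id"].to_numpy(),
            "ca_id": info["ca_id"].to_numpy(),
            "k": k,
            "replicate_supported": k >= 2,
        }
    ).sort_values(["k", "member_id"], ascending=[False, True], ignore_index=True)

    parts = []
    for col, cycle in (("aa_id", 1), ("ca_id", 2)):
        cum = members.groupby(col)["k"].sum()
        parts.append(
            pd.DataFrame({"bb_id": cum.index, "cycle": cycle, "cumulative_k": cum.to_numpy()})
        )
    bb = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["cumulative_k", "bb_id"], ascending=[False, True], ignore_index=True)
        if parts
        else pd.DataFrame(columns=["bb_id", "cycle", "cumulative_k"])
    )
    return KClassTable(
        members=members, bb=bb, screen_label=screen_label, n_catalog_members=catalog.n_members
    )


def _tier(k_high: int, k_low: int, min_k: int, noise_k: int) -> str:
    if k_high >= min_k and k_low >= min_k:
        return "high_priority"
    if k_high >= min_k:
        return "dose_limited"
    if k_high == 0 and k_low == 0:
        return "unobserved"
    return "noise"


@dataclass
class DoseComparisonReport:
    """Per-building-block (and per-disynthon) dose-conformance tiers.

    Tier rules on cumulative k:
      high_priority  — k >= min_k at BOTH UV doses
      dose_limited   — k >= min_k at the high dose only
      noise          — observed, but never reaching min_k at the high dose
                       (includes counts at or below the experimental noise
                       class and the anticonforming low-dose-only pattern)
      unobserved     — no decoded bead at either dose
    """

    bb: pd.DataFrame
    disynthons: pd.DataFrame
    min_k: int
    noise_k: int
    label_high: str
    label_low: str

    def tier_of(self, bb_id: str) -> str:
        row = self.bb.loc[self.bb["bb_id"] == bb_id, "tier"]
        return row.iloc[0] if len(row) else "unobserved"

    def write_tsv(self, path) -> None:
        self.bb.to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        payload = {
            "min_k": self.min_k,
            "noise_k": self.noise_k,
            "label_high": self.label_high,
            "label_low": self.label_low,
            "bb": self.bb.to_dict(orient="records"),
            "disynthons": self.disynthons.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def dose_compare(
    high: KClassTable,
    low: KClassTable,
    min_k: int = DEFAULT_MIN_K,
    noise_k: int = DEFAULT_NOISE_K,
) -> DoseComparisonReport:
    """Tier building blocks by their enrichment at high vs low UV dose.

    Rows are sorted by combined cumulative k (descending), ties broken by
    bb_id; every building block observed at either dose appears exactly
    once.  Disynthon (full member) enrichment is reported for members with
    k >= 2 at either dose.
    """
    if high.n_catalog_members != low.n_catalog_members:
        raise ValueError("k-class tables come from different catalogs")

    hi = high.bb.set_index(["bb_id", "cycle"])["cumulative_k"]
    lo = low.bb.set_index(["bb_id", "cycle"])["cumulative_k"]
    merged = pd.concat([hi.rename("k_high"), lo.rename("k_low")], axis=1).fillna(0).astype(int)
    merged = merged.reset_index()
    merged["tier"] = [
        _tier(kh, kl, min_k, noise_k) for kh, kl in zip(merged["k_high"], merged["k_low"])
    ]
    merged["combined_k"] = merged["k_high"] + merged["k_low"]
    merged = merged.sort_values(
        ["combined_k", "bb_id"], ascending=[False, True], ignore_index=True
    )

    mh = high.members.set_index("member_id")["k"]
    ml = low.members.set_index("member_id")["k"]
    pairs = pd.concat([mh.rename("k_high"), ml.rename("k_low")], axis=1).fillna(0).astype(int)
    pairs = pairs[(pairs["k_high"] >= 2) | (pairs["k_low"] >= 2)].reset_index()
    pairs["tier"] = [
        _tier(kh, kl, min_k, noise_k) for kh, kl in zip(pairs["k_high"], pairs["k_low"])
    ]
    pairs["combined_k"] = pairs["k_high"] + pairs["k_low"]
    pairs = pairs.sort_values(
        ["combined_k", "member_id"], ascending=[False, True], ignore_index=True
    )

    return DoseComparisonReport(
        bb=merged[["bb_id", "cycle", "k_high", "k_low", "combined_k", "tier"]],
        disynthons=pairs[["member_id", "k_high", "k_low", "combined_k", "tier"]],
        min_k=min_k,
        noise_k=noise_k,
        label_high=high.screen_label,
        label_low=low.screen_label,
    )
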