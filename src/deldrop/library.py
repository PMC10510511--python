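"""Combinatorial DEL enumeration, DNA encoding tags, and property profiling.

A two-cycle DNA-encoded library (DEL) combines an amino-acid building
block (cycle 1) with a carboxylic-acid building block (cycle 2) via amide
bond formation; each member carries a DNA tag that is the concatenation of
its two building-block tags.  This module enumerates the full Cartesian
product, validates the encoding tags, and profiles member properties
against fragment-like ("rule of 3") and drug-like ("rule of 5") cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TAG_ALPHABET = "ACGT"
DEFAULT_TAG_LENGTH = 12
DEFAULT_MIN_TAG_DISTANCE = 3

PROPERTY_COLUMNS = ["mw", "clogp", "hbd", "hba", "rotb"]
BB_COLUMNS = ["bb_id", "cycle", "tag"] + PROPERTY_COLUMNS

#: upper thresholds; water lost in amide condensation when combining blocks
WATER_MW = 18.02

RULE_OF_FIVE = {"mw": 500.0, "clogp": 5.0}
RULE_OF_THREE = {"mw": 300.0, "clogp": 3.0, "hbd": 3, "hba": 3, "rotb": 3}


class TagCollisionError(ValueError):
    """Raised when a cycle's tag set contains duplicates."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"tag length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def generate_tags(
    n: int,
    length: int = DEFAULT_TAG_LENGTH,
    min_distance: int = DEFAULT_MIN_TAG_DISTANCE,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sample ``n`` random DNA tags with pairwise Hamming distance >= min_distance.

    Rejection sampling; with 12-mers over a 4-letter alphabet the expected
    pairwise distance is 9, so rejections are rare at the library scales
    used here (a few hundred tags per cycle).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n < 1:
        raise ValueError("need at least one tag")
    if min_distance > length:
        raise ValueError("min_distance cannot exceed tag length")
    alphabet = np.frombuffer(TAG_ALPHABET.encode(), dtype=np.uint8)
    accepted = np.empty((0, length), dtype=np.uint8)
    max_tries = 1000 * n
    tries = 0
    while accepted.shape[0] < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("tag rejection sampling failed to converge")
        cand = alphabet[rng.integers(0, 4, size=length)]
        if accepted.size and int((accepted != cand).sum(axis=1).min()) < min_distance:
            continue
        accepted = np.vstack([accepted, cand])
    return ["".join(map(chr, row)) for row in accepted]


def _validate_tags(bbs: pd.DataFrame, cycle: int) -> None:
    tags = bbs["tag"].astype(str)
    lengths = tags.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"cycle {cycle}: tags must share one length, got {sorted(lengths)}")
    bad = tags[~tags.str.fullmatch(f"[{TAG_ALPHABET}]+")]
    if len(bad):
        raise ValueError(f"cycle {cycle}: non-ACGT tags for {bbs.loc[bad.index, 'bb_id'].tolist()}")
    dup = tags[tags.duplicated(keep=False)]
    if len(dup):
        offenders = bbs.loc[dup.index].groupby("tag")["bb_id"].apply(list).to_dict()
        raise TagCollisionError(f"cycle {cycle}: duplicate tags {offenders}")


def make_building_blocks(
    n: int,
    cycle: int,
    rng: np.random.Generator,
    tag_length: int = DEFAULT_TAG_LENGTH,
    prefix: str | None = None,
) -> pd.DataFrame:
    """Synthesize a building-block table with tags and plausible properties.

    Property distributions are chosen so that the assembled two-cycle
    members are mostly drug-like with a fragment-like shoulder (amino acids
    are heavier on average than the capping carboxylic acids).
    """
    if cycle not in (1, 2):
        raise ValueError("cycle must be 1 (amino acid) or 2 (carboxylic acid)")
    if prefix is None:
        prefix = "AA" if cycle == 1 else "CA"
    width = max(3, len(str(n)))
    if cycle == 1:
        mw = np.clip(rng.normal(240.0, 60.0, n), 90.0, 450.0)
    else:
        mw = np.clip(rng.normal(185.0, 55.0, n), 60.0, 400.0)
    return pd.DataFrame(
        {
            "bb_id": [f"{prefix}{i + 1:0{width}d}" for i in range(n)],
            "cycle": cycle,
            "tag": generate_tags(n, tag_length, rng=rng),
            "mw": np.round(mw, 2),
            "clogp": np.round(rng.normal(0.9, 1.1, n), 2),
            "hbd": rng.poisson(0.9, n),
            "hba": rng.poisson(1.8, n),
            "rotb": rng.poisson(2.2, n),
        }
    )


@dataclass
class LibraryCatalog:
    """Enumerated two-cycle library.

    ``members`` has one row per (amino acid, carboxylic acid) pair in
    amino-acid-major order, i.e. member position = aa_index * ca_count +
    ca_index; that position is the canonical member index used by every
    downstream array (activity maps, bead draws, decode counts).
    """

    aa: pd.DataFrame
    ca: pd.DataFrame
    members: pd.DataFrame = field(repr=False)

    @property
    def aa_count(self) -> int:
        return len(self.aa)

    @property
    def ca_count(self) -> int:
        return len(self.ca)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def tags(self) -> pd.Series:
        return self.members["tag"]

    def member_position(self, aa_idx: np.ndarray, ca_idx: np.ndarray) -> np.ndarray:
        return np.asarray(aa_idx) * self.ca_count + np.asarray(ca_idx)

    def bb_ids_of(self, positions: np.ndarray) -> pd.DataFrame:
        return self.members.iloc[np.asarray(positions)][["member_id", "aa_id", "ca_id"]]

    def write(self, catalog_path, aa_path=None, ca_path=None) -> None:
        self.members.to_csv(catalog_path, sep="\t", index=False)
        if aa_path is not None:
            self.aa.to_csv(aa_path, sep="\t", index=False)
        if ca_path is not None:
            self.ca.to_csv(ca_path, sep="\t", index=False)

    @classmethod
    def read(cls, aa_path, ca_path) -> "LibraryCatalog":
        aa = pd.read_csv(aa_path, sep="\t")
        ca = pd.read_csv(ca_path, sep="\t")
        return enumerate_library(aa, ca)


def enumerate_library(aa_set: pd.DataFrame, ca_set: pd.DataFrame) -> LibraryCatalog:
    """Enumerate the full Cartesian product of two building-block sets.

    Member ordering is amino-acid-major and stable; the member tag is the
    amino-acid tag concatenated with the carboxylic-acid tag.  Member
    properties are a simple additive combination of the block properties
    (molecular weight loses one water to the amide bond; one donor is
    consumed).  Raises :class:`TagCollisionError` on duplicate tags within
    a cycle, identifying the collision.
    """
    for bbs, cyc in ((aa_set, 1), (ca_set, 2)):
        if len(bbs) == 0:
            raise ValueError(f"cycle {cyc} building-block set is empty")
        missing = [c for c in BB_COLUMNS if c not in bbs.columns]
        if missing:
            raise ValueError(f"cycle {cyc} table missing columns {missing}")
        _validate_tags(bbs, cyc)

    na, nc = len(aa_set), len(ca_set)
    ai = np.repeat(np.arange(na), nc)
    ci = np.tile(np.arange(nc), na)
    aa_r = aa_set.iloc[ai].reset_index(drop=True)
    ca_r = ca_set.iloc[ci].reset_index(drop=True)
    members = pd.DataFrame(
        {
            "member_id": aa_r["bb_id"].str.cat(ca_r["bb_id"], sep="-"),
            "aa_id": aa_r["bb_id"].to_numpy(),
            "ca_id": ca_r["bb_id"].to_numpy(),
            "tag": aa_r["tag"].str.cat(ca_r["tag"]),
            "mw": np.round(aa_r["mw"].to_numpy() + ca_r["mw"].to_numpy() - WATER_MW, 2),
            "clogp": np.round(aa_r["clogp"].to_numpy() + ca_r["clogp"].to_numpy(), 2),
            "hbd": np.maximum(aa_r["hbd"].to_numpy() + ca_r["hbd"].to_numpy() - 1, 0),
            "hba": aa_r["hba"].to_numpy() + ca_r["hba"].to_numpy(),
            "rotb": aa_r["rotb"].to_numpy() + ca_r["rotb"].to_numpy(),
        }
    )
    return LibraryCatalog(aa=aa_set.reset_index(drop=True), ca=ca_set.reset_index(drop=True), members=members)


@dataclass
class PropertyProfileSummary:
    """Per-property histograms and fractions passing rule-of-5 / rule-of-3 cuts."""

    fractions: dict[str, float]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    n_members: int


def profile_properties(catalog: LibraryCatalog, bins: int = 40) -> PropertyProfileSummary:
    """Profile member properties against fragment-like and drug-like thresholds.

    Fractions reported: each individual cut (``mw_lt_500``, ``clogp_lt_5``,
    ``mw_lt_300``, ``clogp_lt_3``, ``hbd_le_3``, ``hba_le_3``, ``rotb_le_3``)
    plus the conjunctions ``rule_of_5`` and ``rule_of_3``.
    """
    m = catalog.members
    bad = m[m[PROPERTY_COLUMNS].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"members missing properties: {bad['member_id'].tolist()[:20]}")
    mw = m["mw"].to_numpy(float)
    clogp = m["clogp"].to_numpy(float)
    hbd = m["hbd"].to_numpy(float)
    hba = m["hba"].to_numpy(float)
    rotb = m["rotb"].to_numpy(float)
    if (mw <= 0).any():
        raise ValueError("molecular weights must be positive")

    cuts = {
        "mw_lt_500": mw < RULE_OF_FIVE["mw"],
        "clogp_lt_5": clogp < RULE_OF_FIVE["clogp"],
        "mw_lt_300": mw < RULE_OF_THREE["mw"],
        "clogp_lt_3": clogp < RULE_OF_THREE["clogp"],
        "hbd_le_3": hbd <= RULE_OF_THREE["hbd"],
        "hba_le_3": hba <= RULE_OF_THREE["hba"],
        "rotb_le_3": rotb <= RULE_OF_THREE["rotb"],
    }
    cuts["rule_of_5"] = cuts["mw_lt_500"] & cuts["clogp_lt_5"]
    cuts["rule_of_3"] = (
        cuts["mw_lt_300"] & cuts["clogp_lt_3"] & cuts["hbd_le_3"] & cuts["hba_le_3"] & cuts["rotb_le_3"]
    )
    fractions = {k: float(v.mean()) for k, v in cuts.items()}
    histograms = {p: np.histogram(m[p].to_numpy(float), bins=bins) for p in PROPERTY_COLUMNS}
    return PropertyProfileSummary(fractions=fractions, histograms=histograms, n_members=len(m))
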