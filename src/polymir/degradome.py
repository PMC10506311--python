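"""Degradome (PARE) tag analysis: windows, pairing score, site categories.

Degradome sequencing captures the 5' ends of uncapped mRNA fragments, so
each tag marks a candidate miRNA-guided cleavage position.  Discovery is
tag-anchored: around every tagged position a 26-nt query window (13 nt
upstream, the tagged nucleotide, 12 nt downstream) is extracted and each
miRNA is aligned antiparallel at the two anchorings that place the tagged
position opposite miRNA nucleotide 10 or 11 — the canonical cleavage
register.  Alignments are scored with the standard plant pairing
penalties (mismatch 1, G:U wobble 0.5, doubled at miRNA positions 2-13,
ungapped) and kept at score <= 4.

Retained sites are ranked into categories 0-4 by the tag abundance at
the site relative to the rest of the transcript:

=========  ==========================================================
category   site count > 1 and ...
=========  ==========================================================
0          equal to the transcript maximum, unique maximum
1          equal to the transcript maximum, several maxima
2          below the maximum but above the median
3          at or below the median
4          (site count == 1, regardless of the rest)
=========  ==========================================================

The median is taken over tagged positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW_UP = 13  # nt upstream of the tagged position
WINDOW_DOWN = 12  # nt downstream
WINDOW_LEN = WINDOW_UP + 1 + WINDOW_DOWN
ANCHORS = (10, 11)
SEED_START, SEED_END = 2, 13  # doubled-penalty positions, miRNA 5'->3'

_COMPLEMENT = {"A": "U", "U": "A", "T": "A", "G": "C", "C": "G"}
_VALID = set("ACGUT")


@dataclass
class DegradomeProfile:
    """Per-transcript map of 1-based tag 5'-end positions to read counts."""

    transcript_id: str
    tags: dict[int, int]
    length: int

    def __post_init__(self) -> None:
        for pos, count in self.tags.items():
            if not 1 <= pos <= self.length:
                raise ValueError(
                    f"{self.transcript_id}: tag position {pos} outside 1..{self.length}"
                )
            if count < 1:
                raise ValueError(
                    f"{self.transcript_id}: non-positive tag count at {pos}"
                )

    @property
    def max_count(self) -> int:
        return max(self.tags.values())

    @property
    def n_max(self) -> int:
        m = self.max_count
        return sum(1 for c in self.tags.values() if c == m)

    @property
    def median_count(self) -> float:
        return float(np.median(list(self.tags.values())))


@dataclass(frozen=True)
class QueryWindow:
    transcript_id: str
    position: int  # tagged position, 1-based on the transcript
    start: int  # window start, 1-based
    sequence: str  # 26 nt, tagged nucleotide at offset 14 (1-based)


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    cleavage_pos: int  # tagged transcript coordinate, 1-based
    anchor: int  # miRNA nucleotide (10 or 11) opposite the tag
    score: float
    alignment: str  # per miRNA position 5'->3': '|' pair, 'o' G:U, 'x' mismatch
    count_at_site: int = 0
    tx_max: int = 0
    n_max: int = 0
    tx_median: float = 0.0
    category: int = field(default=-1)


# ---------------------------------------------------------------------------
# profiles and windows
# ---------------------------------------------------------------------------


def build_profiles(
    tags, transcripts: dict[str, str]
) -> tuple[dict[str, DegradomeProfile], int]:
    """Aggregate (transcript, position, count) records into profiles.

    ``tags`` is an iterable of 3-tuples or a DataFrame with columns
    ``transcript_id``, ``position``, ``count``.  Duplicate positions are
    summed.  Returns the profiles plus the number of out-of-bounds
    records dropped; unknown transcript ids are an error.
    """
    if isinstance(tags, pd.DataFrame):
        records = tags[["transcript_id", "position", "count"]].itertuples(index=False)
    else:
        records = tags
    unknown: set[str] = set()
    piles: dict[str, dict[int, int]] = {}
    rejected = 0
    for tx, pos, count in records:
        if tx not in transcripts:
            unknown.add(tx)
            continue
        pos, count = int(pos), int(count)
        if not 1 <= pos <= len(transcripts[tx]):
            rejected += 1
            continue
        piles.setdefault(tx, {})
        piles[tx][pos] = piles[tx].get(pos, 0) + count
    if unknown:
        raise ValueError(f"tags refer to unknown transcript(s): {sorted(unknown)}")
    profiles = {
        tx: DegradomeProfile(tx, pile, len(transcripts[tx]))
        for tx, pile in piles.items()
    }
    return profiles, rejected


def extract_windows(profile: DegradomeProfile, sequence: str) -> list[QueryWindow]:
    """26-nt query windows around each tagged position with full support.

    A position ``p`` yields a window covering transcript ``p-13 .. p+12``
    (1-based, inclusive); positions too close to either end are skipped.
    """
    if len(sequence) != profile.length:
        raise ValueError(
            f"{profile.transcript_id}: sequence length {len(sequence)} != "
            f"profile length {profile.length}"
        )
    windows = []
    for p in sorted(profile.tags):
        start = p - WINDOW_UP
        end = p + WINDOW_DOWN
        if start < 1 or end > profile.length:
            continue
        windows.append(
            QueryWindow(
                transcript_id=profile.transcript_id,
                position=p,
                start=start,
                sequence=sequence[start - 1 : end].upper(),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# pairing score
# ---------------------------------------------------------------------------


def _check_alphabet(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name} contains non-RNA characters: {sorted(bad)}")
    return seq


def _pairs(m: str, t: str) -> bool:
    return _COMPLEMENT[m] == t.replace("T", "U")


def _wobble(m: str, t: str) -> bool:
    m, t = m.replace("T", "U"), t.replace("T", "U")
    return (m, t) in (("G", "U"), ("U", "G"))


def pairing_score(mirna: str, target: str) -> tuple[float, str]:
    """Plant miRNA/target penalty score for an ungapped antiparallel duplex.

    Both sequences run 5'->3' and must have equal length; miRNA position
    ``i`` (1-based from the 5' end) pairs target position ``L - i + 1``.
    Mismatches cost 1.0, G:U wobbles 0.5, and any penalty at miRNA
    positions 2-13 is doubled.  Returns the score and a per-position
    alignment string in miRNA orientation ('|' Watson-Crick, 'o' G:U,
    'x' mismatch).
    """
    mirna = _check_alphabet(mirna, "miRNA")
    target = _check_alphabet(target, "target")
    if len(mirna) != len(target):
        raise ValueError(
            f"miRNA ({len(mirna)} nt) and target ({len(target)} nt) lengths differ"
        )
    n = len(mirna)
    score = 0.0
    marks = []
    for i in range(1, n + 1):
        m = mirna[i - 1]
        t = target[n - i]
        if _pairs(m, t):
            penalty, mark = 0.0, "|"
        elif _wobble(m, t):
            penalty, mark = 0.5, "o"
        else:
            penalty, mark = 1.0, "x"
        if SEED_START <= i <= SEED_END:
            penalty *= 2.0
        score += penalty
        marks.append(mark)
    return score, "".join(marks)


# ---------------------------------------------------------------------------
# site discovery and categorization
# ---------------------------------------------------------------------------


def categorize_site(site: TargetSite, profile: DegradomeProfile) -> int:
    """Assign the 0-4 abundance category of a cleavage site."""
    count = profile.tags.get(site.cleavage_pos)
    if count is None:
        raise ValueError(
            f"site at {site.transcript_id}:{site.cleavage_pos} has no tag"
        )
    if count == 1:
        return 4
    mx = profile.max_count
    med = profile.median_count
    if count == mx:
        return 0 if profile.n_max == 1 else 1
    if count > med:
        return 2
    return 3


def _fill_site_stats(site: TargetSite, profile: DegradomeProfile) -> TargetSite:
    site.count_at_site = profile.tags[site.cleavage_pos]
    site.tx_max = profile.max_count
    site.n_max = profile.n_max
    site.tx_median = profile.median_count
    site.category = categorize_site(site, profile)
    return site


def find_sites(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    max_score: float = 4.0,
) -> list[TargetSite]:
    """Tag-anchored miRNA target discovery over all profiles.

    For every query window and miRNA both cleavage-register anchorings
    (tag opposite miRNA nucleotide 10 and 11) are scored when the implied
    duplex fits inside the window; sites scoring <= ``max_score`` are
    retained with a filled abundance category.  Overlapping anchorings
    that land on the same (miRNA, transcript, position) are deduplicated
    keeping the lower score (anchor 10 on ties).
    """
    best: dict[tuple[str, str, int], TargetSite] = {}
    for tx_id, profile in sorted(profiles.items()):
        seq = transcripts[tx_id]
        for window in extract_windows(profile, seq):
            p = window.position
            for mir_id in sorted(mirnas):
                mir = mirnas[mir_id]
                L = len(mir)
                for anchor in ANCHORS:
                    t_start = p - (L - anchor)  # transcript coords, 1-based
                    t_end = p + (anchor - 1)
                    if t_start < window.start or t_end > window.start + WINDOW_LEN - 1:
                        continue
                    off = t_start - window.start
                    target = window.sequence[off : off + L]
                    score, marks = pairing_score(mir, target)
                    if score > max_score:
                        continue
                    site = TargetSite(
                        mirna_id=mir_id,
                        transcript_id=tx_id,
                        cleavage_pos=p,
                        anchor=anchor,
                        score=score,
                        alignment=marks,
                    )
                    key = (mir_id, tx_id, p)
                    prev = best.get(key)
                    if prev is None or score < prev.score:
                        best[key] = _fill_site_stats(site, profile)
    return sorted(
        best.values(), key=lambda s: (s.transcript_id, s.cleavage_pos, s.mirna_id)
    )


# ---------------------------------------------------------------------------
# t-plots and coverage
# ---------------------------------------------------------------------------


def tplot_table(profile: DegradomeProfile, site: TargetSite) -> pd.DataFrame:
    """Tag abundance by position with the cleavage site flagged (t-plot)."""
    if site.cleavage_pos not in profile.tags:
        raise ValueError("site cleavage position carries no tag")
    rows = [
        {
            "position": pos,
            "count": profile.tags[pos],
            "is_cleavage_site": pos == site.cleavage_pos,
        }
        for pos in sorted(profile.tags)
    ]
    return pd.DataFrame(rows, columns=["position", "count", "is_cleavage_site"])


def plot_tplot(table: pd.DataFrame, ax=None, title: str | None = None):
    """Render a t-plot table with matplotlib; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.vlines(table["position"], 0, table["count"], color="grey", lw=1)
    hit = table[table["is_cleavage_site"]]
    ax.vlines(hit["position"], 0, hit["count"], color="red", lw=2)
    ax.set_xlabel("transcript position (nt)")
    ax.set_ylabel("tag count")
    if title:
        ax.set_title(title)
    return ax


def coverage_stats(profiles, transcripts) -> tuple[int, int, float]:
    """Fraction of input transcripts carrying at least one degradome tag.

    ``transcripts`` may be a mapping or an iterable of transcript ids;
    ``profiles`` a mapping or iterable of profiles.  Returns
    (input count, covered count, percent covered to 2 decimals).
    """
    ids = set(transcripts.keys() if hasattr(transcripts, "keys") else transcripts)
    if not ids:
        raise ValueError("no input transcripts")
    if hasattr(profiles, "values"):
        profs = list(profiles.values())
    else:
        profs = list(profiles)
    covered = {p.transcript_id for p in profs if p.tags} & ids
    percent = round(100.0 * len(covered) / len(ids), 2)
    return len(ids), len(covered), percent
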