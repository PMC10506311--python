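"""Synthetic trio counts, degradome scenarios and hairpin fixtures.

Every generator plants a known ground truth so the downstream callers
can be validated without any sequencing download:

* :func:`generate_trio_counts` emulates a 3-genotype x 3-replicate
  small-RNA (or RNA-seq) design: negative-binomial counts around
  per-genotype means carrying planted additive and non-additive
  features of each pattern category.
* :func:`generate_degradome_scenario` builds random transcripts with
  perfect miRNA complementary sites embedded, and tag piles engineered
  to realize each cleavage-site category over Poisson background decay.
* :func:`generate_hairpin_fixtures` constructs one precursor passing all
  11 screening criteria and, for each criterion, one violating exactly
  that criterion (one documented exception, see
  ``EXPECTED_EXTRA_VIOLATIONS``).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degradome import DegradomeProfile, TargetSite, categorize_site
from .hairpin import HairpinRecord
from .matrix import TrioCountMatrix, make_trio_columns

TRIO_CATEGORIES = ("HP", "LP", "CT44", "CT45", "BP", "additive")

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rand_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def _revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# trio count matrices
# ---------------------------------------------------------------------------


@dataclass
class TrioSimConfig:
    """Study design for the synthetic parent/parent/hybrid count matrix.

    ``planted_counts`` fixes how many features carry each pattern
    category; features not covered are additive background.
    ``effect_log2fc`` is the planted displacement (log2 units) of the
    hybrid from its additive expectation, and also half the parental
    separation for the CT/BP categories.  Dispersion follows the
    mean/dispersion NB parameterization, variance = mu + dispersion*mu^2.
    """

    seed: int
    n_features: int = 1000
    n_replicates: int = 3
    planted_counts: dict[str, int] = field(
        default_factory=lambda: {"HP": 50, "LP": 50, "CT44": 50, "CT45": 50, "BP": 20}
    )
    effect_log2fc: float = 2.0
    dispersion: float = 0.1
    library_size: int = 1_000_000
    baseline_sigma: float = 1.0  # lognormal sd of baseline feature means
    genotypes: dict[str, str] = field(
        default_factory=lambda: {"P1": "T44", "P2": "T45", "H": "H21"}
    )

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_replicates < 1 or self.library_size < 1:
            raise ValueError("n_features, n_replicates, library_size must be positive")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        bad = set(self.planted_counts) - set(TRIO_CATEGORIES)
        if bad:
            raise ValueError(f"unknown planted categories: {sorted(bad)}")
        if any(v < 0 for v in self.planted_counts.values()):
            raise ValueError("planted counts must be non-negative")
        if sum(self.planted_counts.values()) > self.n_features:
            raise ValueError(
                f"planted counts sum to {sum(self.planted_counts.values())} "
                f"> n_features ({self.n_features})"
            )


def _plant_means(
    category: str, b: float, e: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Per-genotype relative mean (P1, P2, H) for one planted feature.

    CT features match the hybrid to the *lower* parent: when the hybrid
    equals the higher of two parents its ratio to the mid-parent value is
    bounded below 2, so |log2FC| > 1 against the MPV is geometrically
    unreachable; matching the lower parent keeps the plant non-additive.
    BP puts the parents 2*effect apart and displaces the hybrid from the
    MPV by the effect toward the lower parent, which keeps it strictly
    between the parents.
    """
    f = 2.0**e
    if category == "HP":
        return b, b, b * f
    if category == "LP":
        return b, b, b / f
    if category == "CT44":
        return b / f, b * f, b / f
    if category == "CT45":
        return b * f, b / f, b / f
    if category == "BP":
        lo, hi = b / f, b * f
        h = (lo + hi) / 2.0 / f
        if rng.random() < 0.5:
            return lo, hi, h
        return hi, lo, h
    # additive: mild random parental offset, hybrid at the mid-parent value
    u = 2.0 ** rng.uniform(-0.5, 0.5)
    p1, p2 = b * u, b / u
    return p1, p2, (p1 + p2) / 2.0


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB counts with variance mu + dispersion*mu^2 (gamma-Poisson)."""
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def generate_trio_counts(
    config: TrioSimConfig,
) -> tuple[TrioCountMatrix, pd.DataFrame]:
    """Simulate the trio count matrix plus its truth table.

    Returns the matrix and a DataFrame indexed by feature id with the
    true category and the relative per-genotype means (arbitrary
    concentration units; each genotype column of counts is scaled so its
    expected total equals ``library_size``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    feature_ids = [f"feat_{i:05d}" for i in range(n)]

    categories = np.array(["additive"] * n, dtype=object)
    order = rng.permutation(n)
    cursor = 0
    for cat in ("HP", "LP", "CT44", "CT45", "BP", "additive"):
        k = config.planted_counts.get(cat, 0)
        categories[order[cursor : cursor + k]] = cat
        cursor += k

    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n)
    means = np.empty((n, 3))  # columns P1, P2, H
    for i in range(n):
        means[i] = _plant_means(
            categories[i], baseline[i], config.effect_log2fc, rng
        )

    cols, roles = make_trio_columns(config.genotypes, config.n_replicates)
    data = np.zeros((n, len(cols)), dtype=np.int64)
    role_index = {"P1": 0, "P2": 1, "H": 2}
    for j, col in enumerate(cols):
        g = role_index[roles[col]]
        scaled = means[:, g] * (config.library_size / means[:, g].sum())
        data[:, j] = _nb_draw(rng, scaled, config.dispersion)

    matrix = TrioCountMatrix(
        counts=pd.DataFrame(data, index=pd.Index(feature_ids, name="feature_id"),
                            columns=cols),
        roles=roles,
    )
    truth = pd.DataFrame(
        {
            "category": categories,
            "mean_P1": means[:, 0],
            "mean_P2": means[:, 1],
            "mean_H": means[:, 2],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# degradome scenarios
# ---------------------------------------------------------------------------


@dataclass
class DegradomeSimConfig:
    """Design of a synthetic degradome experiment with planted sites."""

    seed: int
    n_transcripts: int = 30
    transcript_length_range: tuple[int, int] = (200, 400)
    n_mirnas: int = 8
    mirna_length: int = 21
    planted_sites_per_category: dict[int, int] = field(
        default_factory=lambda: {0: 4, 1: 4, 2: 4, 3: 4, 4: 4}
    )
    background_tag_rate: float = 0.0  # Poisson tags per transcript position
    max_retries: int = 100

    def __post_init__(self) -> None:
        if not 18 <= self.mirna_length <= 25:
            raise ValueError("mirna_length must be within 18-25 nt")
        if self.background_tag_rate < 0:
            raise ValueError("background_tag_rate must be >= 0")
        bad = set(self.planted_sites_per_category) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"unknown site categories: {sorted(bad)}")
        if sum(self.planted_sites_per_category.values()) > self.n_transcripts:
            raise ValueError(
                "more planted sites than transcripts (one site per transcript)"
            )
        lo, hi = self.transcript_length_range
        if lo < 40 or hi < lo:
            raise ValueError("transcript_length_range must be sane and >= 40 nt")


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    transcript_id: str
    position: int  # tagged cleavage position (opposite miRNA nt 10)
    category: int


def _background_tags(
    rng: np.random.Generator, length: int, rate: float, exclude: int
) -> dict[int, int]:
    tags: dict[int, int] = {}
    if rate <= 0:
        return tags
    counts = rng.poisson(rate, size=length)
    for pos0 in np.nonzero(counts)[0]:
        pos = int(pos0) + 1
        if pos != exclude:
            tags[pos] = int(counts[pos0])
    return tags


def _aux_positions(
    rng: np.random.Generator, length: int, taken: set[int], k: int
) -> list[int]:
    free = [p for p in range(1, length + 1) if p not in taken]
    if len(free) < k:
        raise RuntimeError("transcript too short for auxiliary tag piles")
    return [int(p) for p in rng.choice(free, size=k, replace=False)]


def _plant_pile(
    rng: np.random.Generator, category: int, site_pos: int, length: int,
    background: dict[int, int],
) -> dict[int, int]:
    """Tag piles realizing one site category on top of the background."""
    tags = dict(background)
    bg_max = max(tags.values(), default=0)
    taken = set(tags) | {site_pos}
    if category == 0:
        tags[site_pos] = bg_max + 10
    elif category == 1:
        c = bg_max + 10
        tags[site_pos] = c
        tags[_aux_positions(rng, length, taken, 1)[0]] = c
    elif category == 2:
        # median must stay below the site count: add low filler piles
        c = bg_max + 5
        tags[site_pos] = c
        hi, lo1, lo2 = _aux_positions(rng, length, taken, 3)
        tags[hi] = c + 20
        tags[lo1] = 2
        tags[lo2] = 2
    elif category == 3:
        # median must reach the site count: out-pile the low-count positions
        c = 2
        tags[site_pos] = c
        n_low = sum(1 for v in tags.values() if v < c)
        for pos in _aux_positions(rng, length, taken, n_low + 2):
            tags[pos] = bg_max + 10
    elif category == 4:
        tags[site_pos] = 1
        for pos in _aux_positions(rng, length, taken, 1):
            tags[pos] = 5
    else:
        raise ValueError(f"unknown category {category}")
    return tags


def generate_degradome_scenario(
    config: DegradomeSimConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, DegradomeProfile], list[PlantedSite]]:
    """Synthesize transcripts, miRNAs, tag profiles and planted-site truth.

    Each planted site occupies its own transcript: a perfect reverse
    complement of one miRNA is embedded so that the tagged position pairs
    miRNA nucleotide 10, and the tag piles around it realize the
    requested category.  Background decay tags are Poisson per position;
    a bounded retry loop regenerates piles whose category is perturbed by
    the background draw.
    """
    rng = np.random.default_rng(config.seed)
    L = config.mirna_length
    lo, hi = config.transcript_length_range

    mirnas = {
        f"mir_{i + 1:03d}": _rand_rna(rng, L) for i in range(config.n_mirnas)
    }
    mirna_ids = sorted(mirnas)

    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    transcripts = {
        f"tx_{i + 1:04d}": _rand_rna(rng, int(lengths[i]))
        for i in range(config.n_transcripts)
    }
    tx_ids = sorted(transcripts)

    wanted = [
        cat
        for cat in sorted(config.planted_sites_per_category)
        for _ in range(config.planted_sites_per_category[cat])
    ]
    site_tx = [tx_ids[i] for i in rng.permutation(config.n_transcripts)[: len(wanted)]]

    profiles: dict[str, DegradomeProfile] = {}
    truth: list[PlantedSite] = []
    for cat, tx in zip(wanted, site_tx):
        seq = transcripts[tx]
        n = len(seq)
        mir_id = mirna_ids[int(rng.integers(len(mirna_ids)))]
        mir = mirnas[mir_id]
        # tagged position p pairs miRNA nt 10; the duplex spans p-(L-10)..p+9
        # and must sit inside the 26-nt query window (p-13..p+12)
        p = int(rng.integers(14, n - 12 + 1))
        span_start = p - (L - 10)
        chars = list(seq)
        for i in range(1, L + 1):
            t = p + 10 - i  # transcript position paired to miRNA position i
            chars[t - 1] = _RNA_COMPLEMENT[mir[i - 1]]
        seq = "".join(chars)
        transcripts[tx] = seq

        for attempt in range(config.max_retries):
            background = _background_tags(rng, n, config.background_tag_rate, p)
            tags = _plant_pile(rng, cat, p, n, background)
            profile = DegradomeProfile(tx, tags, n)
            probe = TargetSite(
                mirna_id=mir_id, transcript_id=tx, cleavage_pos=p,
                anchor=10, score=0.0, alignment="",
            )
            if categorize_site(probe, profile) == cat:
                profiles[tx] = profile
                break
        else:
            raise RuntimeError(
                f"could not realize category {cat} on {tx} after "
                f"{config.max_retries} attempts"
            )
        truth.append(PlantedSite(mir_id, tx, p, cat))

    # background-only tags on the remaining transcripts
    for tx in tx_ids:
        if tx in profiles or config.background_tag_rate <= 0:
            continue
        tags = _background_tags(rng, len(transcripts[tx]), config.background_tag_rate, 0)
        if tags:
            profiles[tx] = DegradomeProfile(tx, tags, len(transcripts[tx]))

    return transcripts, mirnas, profiles, truth


# ---------------------------------------------------------------------------
# hairpin fixtures
# ---------------------------------------------------------------------------

#: fixtures whose designated violation geometrically forces a second one:
#: a mature region of >= 18 nt with fewer than 12 base pairs necessarily
#: carries >= 7 unpaired nucleotides, so the mature-error bound (<= 4)
#: cannot hold at the same time.
EXPECTED_EXTRA_VIOLATIONS: dict[str, set[str]] = {
    "fail_mature_base_pairs": {"mature_errors"},
}


def _build_hairpin(
    rng: np.random.Generator, elements: list[tuple], loop_len: int
) -> tuple[str, str]:
    """Assemble (sequence, dot-bracket) from outside-in stem elements.

    Elements: ``("bp", n)`` paired run, ``("bulge5", n)`` / ``("bulge3",
    n)`` one-arm bulge, ``("iloop", n5, n3)`` internal loop.
    """
    seq5: list[str] = []
    st5: list[str] = []
    seq3: list[str] = []  # outside-in parts, reversed at assembly
    st3: list[str] = []
    for el in elements:
        kind = el[0]
        if kind == "bp":
            s = _rand_rna(rng, el[1])
            seq5.append(s)
            st5.append("(" * el[1])
            seq3.append(_revcomp_rna(s))
            st3.append(")" * el[1])
        elif kind == "bulge5":
            seq5.append(_rand_rna(rng, el[1]))
            st5.append("." * el[1])
        elif kind == "bulge3":
            seq3.append(_rand_rna(rng, el[1]))
            st3.append("." * el[1])
        elif kind == "iloop":
            seq5.append(_rand_rna(rng, el[1]))
            st5.append("." * el[1])
            seq3.append(_rand_rna(rng, el[2]))
            st3.append("." * el[2])
        else:
            raise ValueError(f"unknown element {kind!r}")
    loop = _rand_rna(rng, loop_len)
    seq = "".join(seq5) + loop + "".join(reversed(seq3))
    struct = "".join(st5) + "." * loop_len + "".join(reversed(st3))
    return seq, struct


def generate_hairpin_fixtures(
    seed: int,
) -> tuple[list[HairpinRecord], dict[str, str]]:
    """Twelve precursor fixtures: one all-pass plus one per criterion.

    Returns the records and a truth map from record id to the violated
    criterion name (or ``"pass"``).  ``fail_mature_base_pairs`` also
    violates ``mature_errors`` (see ``EXPECTED_EXTRA_VIOLATIONS``).
    """
    rng = np.random.default_rng(seed)
    plain = [("bp", 40)]
    designs: list[tuple[str, list[tuple], int, tuple[int, int], float, str]] = [
        ("pass_all", plain, 8, (3, 23), -45.0, "pass"),
        (
            "fail_stem_bulge",
            [("bp", 25), ("iloop", 7, 6), ("bp", 15)],
            8, (3, 23), -45.0, "max_stem_bulge_nt",
        ),
        ("fail_stem_bp", [("bp", 15)], 20, (1, 18), -45.0, "stem_base_pairs"),
        ("fail_energy", plain, 8, (3, 23), -10.0, "free_energy"),
        ("fail_hairpin_length", [("bp", 16)], 4, (1, 18), -45.0, "hairpin_length"),
        ("fail_loop_length", plain, 201, (3, 23), -45.0, "loop_length"),
        (
            "fail_mature_bulge",
            [("bp", 10), ("iloop", 3, 3), ("bp", 30)],
            8, (5, 25), -45.0, "max_mature_bulge_nt",
        ),
        (
            "fail_biased_errors",
            [("bp", 10), ("bulge5", 3), ("bp", 30)],
            8, (5, 25), -45.0, "biased_errors_in_one_mature_bulge",
        ),
        (
            "fail_biased_bulges",
            [("bp", 8), ("bulge5", 1), ("bp", 5), ("bulge5", 1), ("bp", 5),
             ("bulge5", 1), ("bp", 20)],
            8, (5, 25), -45.0, "biased_bulges_in_mature",
        ),
        (
            "fail_mature_errors",
            [("bp", 5), ("iloop", 1, 1), ("bp", 3), ("iloop", 1, 1), ("bp", 3),
             ("iloop", 1, 1), ("bp", 3), ("iloop", 1, 1), ("bp", 3),
             ("iloop", 1, 1), ("bp", 20)],
            8, (3, 23), -45.0, "mature_errors",
        ),
        (
            "fail_mature_base_pairs",
            [("bp", 4), ("iloop", 2, 2), ("bp", 3), ("iloop", 2, 2), ("bp", 3),
             ("iloop", 2, 2), ("bp", 2), ("iloop", 1, 1), ("bp", 20)],
            8, (2, 19), -45.0, "mature_base_pairs",
        ),
        (
            "fail_mature_in_stem",
            [("bp", 30)], 12, (17, 34), -45.0, "mature_in_stem_pct",
        ),
    ]
    records = []
    truth = {}
    for name, elements, loop_len, (m_start, m_end), energy, verdict in designs:
        seq, struct = _build_hairpin(rng, elements, loop_len)
        records.append(
            HairpinRecord(
                id=name, sequence=seq, structure=struct,
                mature_start=m_start, mature_end=m_end, energy=energy,
            )
        )
        truth[name] = verdict
    return records, truth
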