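"""Screening of candidate miRNA precursor hairpins against 11 criteria.

A candidate precursor arrives as a sequence with its dot-bracket
secondary structure (from any folding tool), the coordinates of the
mature miRNA on the precursor, and the folding free energy.  The screen
decomposes the structure into stem, terminal loop and bulges, measures
eleven structural/energetic quantities and applies inclusive thresholds:

====  ==============================================  =========
 #    quantity                                        threshold
====  ==============================================  =========
 1    nucleotides in one stem bulge                   <= 12
 2    base pairs in the stem                          >= 16
 3    free energy (kcal/mol)                          <= -15
 4    hairpin length (stems + loop + bulges)          >= 50
 5    terminal loop length                            <= 200
 6    nucleotides in one bulge in the mature region   <= 4
 7    biased errors in one mature-region bulge        <= 2
 8    biased bulges in the mature region              <= 2
 9    errors (unpaired nt) in the mature region       <= 4
10    base pairs in the mature region                 >= 12
11    percent of the mature sequence in the stem      >= 80
====  ==============================================  =========

Terminology used here: an "error" is an unpaired nucleotide; a bulge is
"biased" when its unpaired nucleotides fall on one arm only, and its
"biased errors" are the unpaired nucleotides on its majority arm.  A
mature-region bulge is any bulge whose unpaired nucleotides overlap the
mature interval.  "In the stem" counts both paired nucleotides and
nucleotides inside stem bulges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CRITERIA = (
    "max_stem_bulge_nt",
    "stem_base_pairs",
    "free_energy",
    "hairpin_length",
    "loop_length",
    "max_mature_bulge_nt",
    "biased_errors_in_one_mature_bulge",
    "biased_bulges_in_mature",
    "mature_errors",
    "mature_base_pairs",
    "mature_in_stem_pct",
)

THRESHOLDS = {
    "max_stem_bulge_nt": ("<=", 12),
    "stem_base_pairs": (">=", 16),
    "free_energy": ("<=", -15.0),
    "hairpin_length": (">=", 50),
    "loop_length": ("<=", 200),
    "max_mature_bulge_nt": ("<=", 4),
    "biased_errors_in_one_mature_bulge": ("<=", 2),
    "biased_bulges_in_mature": ("<=", 2),
    "mature_errors": ("<=", 4),
    "mature_base_pairs": (">=", 12),
    "mature_in_stem_pct": (">=", 80.0),
}


@dataclass
class HairpinRecord:
    """Candidate precursor: sequence, structure, mature arm, energy."""

    id: str
    sequence: str
    structure: str
    mature_start: int  # 1-based, inclusive
    mature_end: int
    energy: float  # kcal/mol

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.id}: sequence and structure lengths differ "
                f"({len(self.sequence)} vs {len(self.structure)})"
            )
        if not 1 <= self.mature_start <= self.mature_end <= len(self.sequence):
            raise ValueError(f"{self.id}: mature interval outside the precursor")

    @property
    def mature_length(self) -> int:
        return self.mature_end - self.mature_start + 1


@dataclass(frozen=True)
class Bulge:
    """Unpaired run(s) between two consecutive stem pairs."""

    positions_5p: tuple[int, ...]
    positions_3p: tuple[int, ...]

    @property
    def nt(self) -> int:
        return len(self.positions_5p) + len(self.positions_3p)

    @property
    def biased(self) -> bool:
        return (len(self.positions_5p) == 0) != (len(self.positions_3p) == 0)

    @property
    def positions(self) -> tuple[int, ...]:
        return self.positions_5p + self.positions_3p

    def majority_arm_nt(self) -> int:
        return max(len(self.positions_5p), len(self.positions_3p))


@dataclass
class HairpinDecomposition:
    pairs: list[tuple[int, int]]  # (5' pos, 3' pos), outermost first
    loop_positions: tuple[int, ...]
    bulges: list[Bulge]

    @property
    def stem_base_pairs(self) -> int:
        return len(self.pairs)

    @property
    def loop_length(self) -> int:
        return len(self.loop_positions)

    def stem_positions(self) -> set[int]:
        """All positions between the outermost pair and the loop: paired
        nucleotides plus stem-bulge nucleotides."""
        pos = {p for pair in self.pairs for p in pair}
        for b in self.bulges:
            pos.update(b.positions)
        return pos

    @property
    def hairpin_length(self) -> int:
        return 2 * self.stem_base_pairs + self.loop_length + sum(
            b.nt for b in self.bulges
        )


@dataclass
class CriteriaVerdict:
    values: dict[str, float]
    passed: dict[str, bool]
    overall: bool = field(init=False)

    def __post_init__(self) -> None:
        self.overall = all(self.passed[c] for c in CRITERIA)

    def failed(self) -> list[str]:
        return [c for c in CRITERIA if not self.passed[c]]


# ---------------------------------------------------------------------------
# structure parsing
# ---------------------------------------------------------------------------


def parse_structure(dotbracket: str) -> dict[int, int | None]:
    """Dot-bracket to a 1-based pair table (position -> partner or None)."""
    table: dict[int, int | None] = {}
    stack: list[int] = []
    for i, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(i)
            table[i] = None
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i] = j
            table[j] = i
        elif ch == ".":
            table[i] = None
        else:
            raise ValueError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[0]}")
    return table


def decompose(pair_table: dict[int, int | None]) -> HairpinDecomposition:
    """Split a single-hairpin pair table into stem, loop and bulges.

    Rejects multi-loop structures: every pair must enclose the next one,
    so the pairs form one nested stack around one terminal loop.
    """
    pairs = sorted(
        (i, j) for i, j in pair_table.items() if j is not None and i < j
    )
    if not pairs:
        raise ValueError("not a hairpin: no base pairs")
    # nesting check: 5' positions ascend (sorted), 3' partners must descend
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 < j2 < j1):
            raise ValueError("not a simple hairpin (multiloop or parallel stems)")
    bulges: list[Bulge] = []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        run5 = tuple(range(i1 + 1, i2))
        run3 = tuple(range(j2 + 1, j1))
        if run5 or run3:
            bulges.append(Bulge(positions_5p=run5, positions_3p=run3))
    inner_i, inner_j = pairs[-1]
    loop = tuple(range(inner_i + 1, inner_j))
    return HairpinDecomposition(pairs=pairs, loop_positions=loop, bulges=bulges)


# ---------------------------------------------------------------------------
# criteria evaluation
# ---------------------------------------------------------------------------


def mature_arm(record: HairpinRecord, decomp: HairpinDecomposition) -> str:
    """5p if the mature midpoint lies before the terminal loop, else 3p."""
    mid = (record.mature_start + record.mature_end) / 2
    loop_mid = (
        (decomp.loop_positions[0] + decomp.loop_positions[-1]) / 2
        if decomp.loop_positions
        else (decomp.pairs[-1][0] + decomp.pairs[-1][1]) / 2
    )
    return "5p" if mid < loop_mid else "3p"


def _check(name: str, value: float) -> bool:
    op, threshold = THRESHOLDS[name]
    return value <= threshold if op == "<=" else value >= threshold


def evaluate_criteria(record: HairpinRecord) -> CriteriaVerdict:
    """Measure all 11 quantities for a record and apply the thresholds."""
    if not 18 <= record.mature_length <= 25:
        raise ValueError(
            f"{record.id}: mature length {record.mature_length} outside 18-25 nt"
        )
    table = parse_structure(record.structure)
    decomp = decompose(table)
    mature = set(range(record.mature_start, record.mature_end + 1))

    mature_bulges = [b for b in decomp.bulges if mature & set(b.positions)]
    biased_mature = [b for b in mature_bulges if b.biased]
    paired_in_mature = sum(1 for p in mature if table[p] is not None)
    errors_in_mature = record.mature_length - paired_in_mature
    in_stem = len(mature & decomp.stem_positions())

    values: dict[str, float] = {
        "max_stem_bulge_nt": max((b.nt for b in decomp.bulges), default=0),
        "stem_base_pairs": decomp.stem_base_pairs,
        "free_energy": record.energy,
        "hairpin_length": decomp.hairpin_length,
        "loop_length": decomp.loop_length,
        "max_mature_bulge_nt": max((b.nt for b in mature_bulges), default=0),
        "biased_errors_in_one_mature_bulge": max(
            (b.majority_arm_nt() for b in biased_mature), default=0
        ),
        "biased_bulges_in_mature": len(biased_mature),
        "mature_errors": errors_in_mature,
        "mature_base_pairs": paired_in_mature,
        "mature_in_stem_pct": round(100.0 * in_stem / record.mature_length, 2),
    }
    passed = {name: _check(name, values[name]) for name in CRITERIA}
    return CriteriaVerdict(values=values, passed=passed)
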