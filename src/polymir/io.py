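"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are TSV (header row, UTF-8, LF) and all coordinates
are 1-based inclusive.  Sequences travel as FASTA; miRNAs may use either
U or T — pairing treats them as equivalent — and are emitted as given.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .degradome import DegradomeProfile, TargetSite, build_profiles
from .hairpin import CRITERIA, CriteriaVerdict, HairpinRecord
from .matrix import TrioCountMatrix
from .nonadditive import VennDecomposition


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """FASTA to an id -> uppercased-sequence map; duplicate ids error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_counts(path, role_map: dict[str, str]) -> TrioCountMatrix:
    """Counts TSV (feature_id + `<genotype>_<rep>` columns) to a matrix.

    ``role_map`` maps genotype labels to roles, e.g. ``{"T44": "P1",
    "T45": "P2", "H21": "H"}``.
    """
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    roles = {}
    for col in df.columns:
        genotype = col.rsplit("_", 1)[0]
        if genotype not in role_map:
            raise ValueError(
                f"{path}: column {col!r} has genotype {genotype!r} not in the "
                f"role map {sorted(role_map)}"
            )
        roles[col] = role_map[genotype]
    if df.isna().any().any():
        r, c = next(zip(*df.isna().to_numpy().nonzero()))
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, "
                         f"column {df.columns[c]!r}")
    try:
        counts = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer count ({exc})") from exc
    return TrioCountMatrix(counts=counts, roles=roles)


def write_counts(matrix: TrioCountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# degradome tags and sites
# ---------------------------------------------------------------------------


def read_tags(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["transcript_id", "position", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def write_tags(profiles: dict[str, DegradomeProfile], path) -> None:
    rows = [
        {"transcript_id": tx, "position": pos, "count": prof.tags[pos]}
        for tx, prof in sorted(profiles.items())
        for pos in sorted(prof.tags)
    ]
    pd.DataFrame(rows, columns=["transcript_id", "position", "count"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_profiles(tags_path, transcripts: dict[str, str]):
    return build_profiles(read_tags(tags_path), transcripts)


SITE_COLUMNS = [
    "mirna_id", "transcript_id", "cleavage_pos", "anchor", "score",
    "count_at_site", "tx_max", "n_max", "tx_median", "category", "alignment",
]


def sites_frame(sites: list[TargetSite]) -> pd.DataFrame:
    rows = [{k: getattr(s, k) for k in SITE_COLUMNS} for s in sites]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_sites(sites: list[TargetSite], path) -> None:
    sites_frame(sites).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# hairpins and verdicts
# ---------------------------------------------------------------------------

HAIRPIN_COLUMNS = ["id", "sequence", "structure", "mature_start", "mature_end", "energy"]


def read_hairpins(path) -> list[HairpinRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(HAIRPIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        HairpinRecord(
            id=row.id, sequence=row.sequence, structure=row.structure,
            mature_start=int(row.mature_start), mature_end=int(row.mature_end),
            energy=float(row.energy),
        )
        for row in df.itertuples(index=False)
    ]


def write_hairpins(records: list[HairpinRecord], path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=HAIRPIN_COLUMNS
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_verdicts(verdicts: dict[str, CriteriaVerdict], path) -> None:
    rows = []
    for name, v in verdicts.items():
        row: dict[str, object] = {"id": name}
        for c in CRITERIA:
            row[c] = v.values[c]
            row[f"{c}_pass"] = v.passed[c]
        row["overall_pass"] = v.overall
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# calls, Venn, truth
# ---------------------------------------------------------------------------


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_venn(venn: VennDecomposition, path) -> None:
    rows = [{"region": k, "size": v} for k, v in venn.regions().items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# run summary
# ---------------------------------------------------------------------------


def report(
    calls: pd.DataFrame | None = None,
    venn: VennDecomposition | None = None,
    sites: pd.DataFrame | None = None,
    verdicts: dict[str, CriteriaVerdict] | None = None,
) -> str:
    """Deterministic plain-text tally of a pipeline run."""
    lines: list[str] = ["# polymir run summary"]
    if calls is not None:
        non = calls[calls["additivity"] == "non-additive"]
        lines.append(f"features tested\t{len(calls)}")
        lines.append(f"non-additive\t{len(non)}")
        for cat in ("HP", "LP", "CT44", "CT45", "BP", "unclassified"):
            lines.append(f"category {cat}\t{int((non['category'] == cat).sum())}")
    if venn is not None:
        for region, size in venn.regions().items():
            lines.append(f"venn {region}\t{size}")
    if sites is not None:
        lines.append(f"target sites\t{len(sites)}")
        for cat in range(5):
            lines.append(f"degradome category {cat}\t"
                         f"{int((sites['category'] == cat).sum())}")
    if verdicts is not None:
        passed = sum(1 for v in verdicts.values() if v.overall)
        lines.append(f"hairpins screened\t{len(verdicts)}")
        lines.append(f"hairpins passing\t{passed}")
    return "\n".join(lines) + "\n"


def sha256_of(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
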