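"""Count-matrix container for a parent/parent/hybrid expression trio.

A trio experiment measures the same features (miRNAs or genes) in two
parental lines and their hybrid, each with replicated libraries.  The
container keeps raw counts, the genotype role of every sample column
(``P1``, ``P2`` or ``H``) and, once computed, a reads-per-million layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("P1", "P2", "H")


@dataclass
class TrioCountMatrix:
    """Features x samples count matrix with genotype-role annotation.

    Parameters
    ----------
    counts:
        Non-negative integer counts, one row per feature, one column per
        sample.  Sample columns are named ``<genotype>_<replicate>``.
    roles:
        Mapping of sample column name to genotype role (``P1``, ``P2``
        or ``H``).
    rpm:
        Optional reads-per-million normalized layer with the same shape
        as ``counts``.
    """

    counts: pd.DataFrame
    roles: dict[str, str]
    rpm: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        missing = [c for c in self.counts.columns if c not in self.roles]
        if missing:
            raise ValueError(f"samples without a genotype role: {missing}")
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown genotype roles: {sorted(bad)}; expected {ROLES}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    # -- basic accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    def samples(self, role: str) -> list[str]:
        """Sample columns carrying the given genotype role, in column order."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [c for c in self.counts.columns if self.roles[c] == role]

    def role_counts(self) -> dict[str, int]:
        return {r: len(self.samples(r)) for r in ROLES}

    def require_replicates(self, minimum: int = 2) -> None:
        for role, n in self.role_counts().items():
            if n < minimum:
                raise ValueError(
                    f"role {role} has {n} replicate(s); at least {minimum} required"
                )

    def rpm_or_raise(self) -> pd.DataFrame:
        if self.rpm is None:
            raise ValueError("matrix has no RPM layer; call normalize_rpm first")
        return self.rpm

    def copy(self) -> "TrioCountMatrix":
        return TrioCountMatrix(
            counts=self.counts.copy(),
            roles=dict(self.roles),
            rpm=None if self.rpm is None else self.rpm.copy(),
        )

    def swap_parents(self) -> "TrioCountMatrix":
        """Relabel P1 columns as P2 and vice versa (columns untouched)."""
        flip = {"P1": "P2", "P2": "P1", "H": "H"}
        return TrioCountMatrix(
            counts=self.counts.copy(),
            roles={s: flip[r] for s, r in self.roles.items()},
            rpm=None if self.rpm is None else self.rpm.copy(),
        )


def sample_name(genotype: str, replicate: int) -> str:
    return f"{genotype}_{replicate}"


def make_trio_columns(
    genotypes: dict[str, str], n_replicates: int
) -> tuple[list[str], dict[str, str]]:
    """Build ordered sample names and their role map.

    ``genotypes`` maps role -> genotype label, e.g. ``{"P1": "T44"}``.
    """
    cols: list[str] = []
    roles: dict[str, str] = {}
    for role in ROLES:
        label = genotypes[role]
        for rep in range(1, n_replicates + 1):
            name = sample_name(label, rep)
            cols.append(name)
            roles[name] = role
    return cols, roles


def as_int_counts(values: np.ndarray) -> np.ndarray:
    out = np.asarray(values)
    if not np.issubdtype(out.dtype, np.integer):
        rounded = np.rint(out)
        if not np.allclose(out, rounded):
            raise ValueError("counts must be integers")
        out = rounded.astype(np.int64)
    return out.astype(np.int64)
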