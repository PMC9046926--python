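"""Core in-memory containers for the 2x2 (group x condition) design.

A :class:`CountMatrix` couples an integer gene x sample table with per-sample
annotations (group in {G1, G2}, condition in {Ctrl, Treated}); a
:class:`GroundTruth` records the simulator's per-gene coefficients;
a :class:`GeneSetCollection` is a GMT-shaped list of named gene sets with
optional truth labels; a :class:`VennPartition` is the four-way decomposition
of two DEG lists within a tested universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from degvenn.errors import ValidationError

GROUPS = ("G1", "G2")
CONDITIONS = ("Ctrl", "Treated")


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count table with sample annotations.

    Parameters
    ----------
    counts
        DataFrame with genes as the index and samples as columns; all cells
        must be nonnegative integers.
    annotation
        DataFrame indexed by sample id with columns ``group`` and
        ``condition``; samples must match the count columns exactly and every
        one of the four group x condition cells must be non-empty.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers in count matrix")
        missing = set(self.counts.columns) ^ set(self.annotation.index)
        if missing:
            raise ValidationError(
                f"count columns and annotation samples differ: {sorted(missing)!r}"
            )
        # align annotation rows to count column order
        self.annotation = self.annotation.loc[self.counts.columns]
        for col in ("group", "condition"):
            if col not in self.annotation.columns:
                raise ValidationError(f"annotation lacks required column {col!r}")
        bad_group = set(self.annotation["group"]) - set(GROUPS)
        bad_cond = set(self.annotation["condition"]) - set(CONDITIONS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        if bad_cond:
            raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be nonnegative")
        for g in GROUPS:
            for c in CONDITIONS:
                n = int(
                    (
                        (self.annotation["group"] == g)
                        & (self.annotation["condition"] == c)
                    ).sum()
                )
                if n == 0:
                    raise ValidationError(f"design cell {g}/{c} is empty")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def design_matrix(self) -> pd.DataFrame:
        """Full-rank treatment-coded design: intercept, group, condition, group:condition."""
        group = (self.annotation["group"] == "G2").astype(float)
        cond = (self.annotation["condition"] == "Treated").astype(float)
        return pd.DataFrame(
            {
                "intercept": 1.0,
                "group": group,
                "condition": cond,
                "group:condition": group * cond,
            },
            index=self.annotation.index,
        )


@dataclass
class GroundTruth:
    """Simulator truth: per-gene coefficients and flags, per-sample size factors.

    ``genes`` has one row per gene with columns ``mu`` (baseline mean),
    ``lfc_g1``/``lfc_g2`` (true treatment log2 fold changes per group),
    ``is_de_shared`` and ``has_interaction``; ``size_factors`` is a Series
    indexed by sample id.
    """

    genes: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        required = {"mu", "lfc_g1", "lfc_g2", "is_de_shared", "has_interaction"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValidationError(f"truth table lacks columns {sorted(missing)}")

    @property
    def de_genes(self) -> frozenset[str]:
        """Genes with a nonzero true treatment effect in both groups."""
        mask = (self.genes["lfc_g1"] != 0) & (self.genes["lfc_g2"] != 0)
        return frozenset(self.genes.index[mask])


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")
        if len(self.members) < 1:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets, GMT-shaped.

    ``labels`` optionally tags synthetic sets as ``"response"`` (built around
    truly treatment-responsive genes) or ``"background"`` (random members).
    """

    sets: list[GeneSet]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene set names in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def label(self, name: str) -> str | None:
        return self.labels.get(name)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint four-way split of a universe by two gene sets."""

    only_a: frozenset[str]
    only_b: frozenset[str]
    both: frozenset[str]
    neither: frozenset[str]

    @property
    def universe(self) -> frozenset[str]:
        return self.only_a | self.only_b | self.both | self.neither

    def counts(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "both": len(self.both),
            "neither": len(self.neither),
        }
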