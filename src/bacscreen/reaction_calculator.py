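"""Reaction-count and cost accounting for pooled 2-D PCR-HRM screens.

For a library of N 384-well plates, anchoring one marker takes N/25
superpool reactions, 10 matrix-pool reactions for the positive superpool,
and 18 single-plate-pool reactions for the positive plate — N/25 + 28 in
total — versus N/10 + 50 for the conventional-PCR 3-D comparator (10-plate
superpools, 10 matrix + 40 single-pool reactions).

``budget_paper_mode`` reproduces the published whole-library accounting for
3 markers: the superpool stage is multiplexed (one pass for all markers,
zero reactions when the library fits a single superpool), each positive
superpool takes one 10-pool matrix screen, markers are assumed to land in
distinct superpools/plates when possible, and the 18-pool plate screen is
per marker.  Triplexing divides the total by 3, rounded up.  ``strict``
mode instead charges every stage per marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from bacscreen.library_model import (
    GenomeSpec,
    RoundingMode,
    paper_round,
    required_clone_count,
    required_plate_count,
)

__all__ = [
    "ScreeningBudget",
    "CostModel",
    "budget_paper_mode",
    "budget_strict_mode",
    "budget_single_marker",
    "budget_conventional_3d",
    "cost_estimate",
    "render_table2",
    "PUBLISHED_TABLE2",
]

MATRIX_POOLS = 10       # 5x5 plate grid: 5 H + 5 V pools
SINGLE_PLATE_POOLS = 18  # 8 row pools + 10 column pools
CONVENTIONAL_SINGLE_PLATE_POOLS = 40
MAX_PLATES_PER_SUPERPOOL = 25
CONVENTIONAL_MAX_PLATES_PER_SUPERPOOL = 10
MAX_MULTIPLEX = 3


@dataclass(frozen=True)
class ScreeningBudget:
    """Reaction counts for anchoring ``n_markers`` markers in an N-plate library."""

    n_plates: int
    n_superpools: int
    n_markers: int
    superpool_stage_reactions: int
    matrix_stage_reactions: int
    single_stage_reactions: int

    def __post_init__(self) -> None:
        for name in ("superpool_stage_reactions", "matrix_stage_reactions",
                     "single_stage_reactions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_simplex(self) -> int:
        return (self.superpool_stage_reactions + self.matrix_stage_reactions
                + self.single_stage_reactions)

    @property
    def total_triplex(self) -> int:
        return math.ceil(self.total_simplex / MAX_MULTIPLEX)


@dataclass(frozen=True)
class CostModel:
    """Per-reaction consumable costs in GBP."""

    cost_per_pcr_hrm: float = 0.17
    cost_per_conventional_pcr: float = 0.16

    def __post_init__(self) -> None:
        if self.cost_per_pcr_hrm <= 0 or self.cost_per_conventional_pcr <= 0:
            raise ValueError("costs must be positive")


def budget_paper_mode(n_plates: int, n_markers: int = 3) -> ScreeningBudget:
    """Whole-library budget under the published accounting conventions.

    Superpool count is ``round(N/25)`` (at least 1).  Stage reactions:

    * superpool stage: one reaction per superpool, multiplexed across
      markers; contributes 0 when there is a single superpool (nothing to
      distinguish);
    * matrix stage: 10 reactions per positive superpool, assuming the
      markers occupy distinct superpools when there are enough of them;
    * single-plate stage: 18 reactions per marker (markers assumed on
      distinct plates).
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if not 1 <= n_markers:
        raise ValueError("n_markers must be >= 1")
    n_superpools = max(1, paper_round(n_plates / MAX_PLATES_PER_SUPERPOOL))
    superpool_stage = n_superpools if n_superpools > 1 else 0
    matrix_stage = MATRIX_POOLS * min(n_markers, n_superpools)
    single_stage = SINGLE_PLATE_POOLS * n_markers
    return ScreeningBudget(
        n_plates=n_plates,
        n_superpools=n_superpools,
        n_markers=n_markers,
        superpool_stage_reactions=superpool_stage,
        matrix_stage_reactions=matrix_stage,
        single_stage_reactions=single_stage,
    )


def budget_strict_mode(n_plates: int, n_markers: int = 3) -> ScreeningBudget:
    """Self-consistent per-marker accounting: every stage charged per marker,
    superpool count rounded up, superpool stage never skipped."""
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    n_superpools = math.ceil(n_plates / MAX_PLATES_PER_SUPERPOOL)
    return ScreeningBudget(
        n_plates=n_plates,
        n_superpools=n_superpools,
        n_markers=n_markers,
        superpool_stage_reactions=n_superpools * n_markers,
        matrix_stage_reactions=MATRIX_POOLS * n_markers,
        single_stage_reactions=SINGLE_PLATE_POOLS * n_markers,
    )


def budget_single_marker(n_plates: int) -> dict[str, float]:
    """Symbolic per-marker budget of the 2-D scheme: N/25 + 10 + 18.

    The superpool component is left fractional, as in the published
    symbolic form N/25 + 28.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    superpool = n_plates / MAX_PLATES_PER_SUPERPOOL
    return {
        "superpool": superpool,
        "matrix": MATRIX_POOLS,
        "single_plate": SINGLE_PLATE_POOLS,
        "post_superpool": MATRIX_POOLS + SINGLE_PLATE_POOLS,
        "total": superpool + MATRIX_POOLS + SINGLE_PLATE_POOLS,
    }


def budget_conventional_3d(n_plates: int) -> dict[str, float]:
    """Per-marker budget of the conventional-PCR 3-D comparator: N/10 + 50."""
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    superpool = n_plates / CONVENTIONAL_MAX_PLATES_PER_SUPERPOOL
    return {
        "superpool": superpool,
        "matrix": MATRIX_POOLS,
        "single_plate": CONVENTIONAL_SINGLE_PLATE_POOLS,
        "post_superpool": MATRIX_POOLS + CONVENTIONAL_SINGLE_PLATE_POOLS,
        "total": superpool + MATRIX_POOLS + CONVENTIONAL_SINGLE_PLATE_POOLS,
    }


def cost_estimate(
    budget: ScreeningBudget, cost_model: CostModel | None = None
) -> dict[str, object]:
    """Consumable cost of a budget under each chemistry.

    The conventional-PCR figure excludes agarose-gel electrophoresis, which
    that workflow additionally requires; the flag records this.
    """
    cm = cost_model or CostModel()
    return {
        "pcr_hrm_simplex_gbp": round(budget.total_simplex * cm.cost_per_pcr_hrm, 2),
        "pcr_hrm_triplex_gbp": round(budget.total_triplex * cm.cost_per_pcr_hrm, 2),
        "conventional_gbp": round(
            budget.total_simplex * cm.cost_per_conventional_pcr, 2
        ),
        "conventional_excludes_gel_electrophoresis": True,
    }


# Published reference rows: organism -> (1C genome Mb, plates, superpools,
# matrix pools, single pools, total simplex, total triplex).  Used only to
# report where recomputation disagrees with the printed table.
PUBLISHED_TABLE2: dict[str, tuple[int, int, int, int, int, int, int]] = {
    "Brachypodium distachyon": (300, 24, 1, 10, 54, 64, 22),
    "Potato": (850, 66, 3, 30, 54, 87, 29),
    "Barley": (5500, 430, 17, 30, 54, 101, 35),
    "Wheat": (16000, 1250, 50, 30, 54, 134, 45),
    "Swine": (2600, 203, 8, 30, 54, 92, 31),
    "Cattle": (3100, 242, 10, 30, 54, 94, 32),
}

_TABLE2_COLUMNS = [
    "organism", "genome_mb", "n_plates", "n_superpools",
    "matrix_pools", "single_pools", "total_simplex", "total_triplex",
]


def render_table2(
    genomes: list[tuple[str, float]] | None = None,
    coverage: float = 3.0,
    mean_insert: int = 100_000,
    mode: RoundingMode = RoundingMode.PAPER_ROUND,
) -> tuple[pd.DataFrame, list[str]]:
    """Recompute the per-genome screening-budget table for 3 markers.

    ``genomes`` is a list of (name, genome size in Mb); defaults to the six
    published reference genomes.  Returns the recomputed table and a list
    of explicit mismatch notes against the published values (for genomes
    present in the reference); mismatches are reported, never hidden.
    """
    if genomes is None:
        genomes = [(name, row[0]) for name, row in PUBLISHED_TABLE2.items()]
    records = []
    mismatches: list[str] = []
    for name, genome_mb in genomes:
        spec = GenomeSpec(
            genome_size=int(round(genome_mb * 1e6)),
            coverage=coverage,
            mean_insert=mean_insert,
        )
        clones = required_clone_count(spec)
        plates = required_plate_count(clones, mode=mode)
        budget = budget_paper_mode(plates)
        records.append({
            "organism": name,
            "genome_mb": genome_mb,
            "n_plates": plates,
            "n_superpools": budget.n_superpools,
            "matrix_pools": budget.matrix_stage_reactions,
            "single_pools": budget.single_stage_reactions,
            "total_simplex": budget.total_simplex,
            "total_triplex": budget.total_triplex,
        })
        if name in PUBLISHED_TABLE2:
            ref = PUBLISHED_TABLE2[name]
            computed = (plates, budget.n_superpools,
                        budget.matrix_stage_reactions,
                        budget.single_stage_reactions,
                        budget.total_simplex, budget.total_triplex)
            for col, got, want in zip(_TABLE2_COLUMNS[2:], computed, ref[1:]):
                if got != want:
                    mismatches.append(
                        f"{name}: {col} computed {got} vs published {want}"
                    )
    df = pd.DataFrame.from_records(records, columns=_TABLE2_COLUMNS)
    return df, mismatches
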