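"""Three-tier pooling designs: superpools, matrix pools, single-plate pools.

The screen proceeds top-down.  Superpools combine the freezer stocks of up
to 25 whole 384-well plates; one PCR per superpool finds the positive
superpool.  The plates of a positive superpool are laid out on a near-square
grid and pooled by grid row (H pools) and grid column (V pools); one
positive H and one positive V pool intersect at the positive plate.  The
positive plate is then resolved to a well by overlapping row and column
pools: each of the 16 plate rows belongs to exactly 2 of 8 row pools (4 rows
per pool) and each of the 24 columns to exactly 2 of 10 column pools (6
pools of 4 columns, 4 pools of 6), so a positive well lights up exactly two
row pools and two column pools, and the pair of positives per dimension is
unique to one row/column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from bacscreen.library_model import (
    LibraryLayout,
    PlateFormat,
    RoundingMode,
    WellAddress,
)

__all__ = [
    "SuperpoolDesign",
    "MatrixDesign",
    "SinglePlateDesign",
    "PoolManifest",
    "ValidationReport",
    "build_superpools",
    "build_matrix_design",
    "build_single_plate_design",
    "validate_design",
    "pool_volume",
    "superpool_manifest",
    "matrix_pool_manifests",
    "single_plate_manifests",
]

DEFAULT_ALIQUOT_UL = 5.0


@dataclass(frozen=True)
class SuperpoolDesign:
    """Partition of library plates into superpools of at most ``max_plates``.

    ``assignment`` maps every plate ID to its superpool ID (1-based,
    consecutive blocks of plates).  ``reported_count`` carries the count
    under the requested rounding mode, which for the half-up convention can
    differ from the number of physical superpools actually assigned.
    """

    max_plates_per_superpool: int
    assignment: dict[int, int]
    n_superpools: int
    reported_count: int

    def plates_in(self, superpool_id: int) -> list[int]:
        return sorted(p for p, s in self.assignment.items() if s == superpool_id)

    @property
    def superpool_ids(self) -> range:
        return range(1, self.n_superpools + 1)


@dataclass(frozen=True)
class MatrixDesign:
    """Grid layout of one superpool's plates with H (row) and V (column) pools.

    Plates are numbered 1..n within the superpool and placed row-major on a
    ``g_rows x g_cols`` grid; pool ``H{i}`` holds grid row i, ``V{j}`` grid
    column j.  A single-plate superpool needs no matrix stage
    (``skip_stage`` is set and there are no pools).
    """

    n_plates: int
    g_rows: int
    g_cols: int
    h_pools: dict[str, tuple[int, ...]]
    v_pools: dict[str, tuple[int, ...]]
    skip_stage: bool = False

    @property
    def n_pools(self) -> int:
        return len(self.h_pools) + len(self.v_pools)

    @property
    def pool_ids(self) -> list[str]:
        return list(self.h_pools) + list(self.v_pools)

    def membership(self, plate: int) -> tuple[str, str]:
        """The (H, V) pool pair of a plate (1-based within the superpool)."""
        if not 1 <= plate <= self.n_plates:
            raise ValueError(f"plate {plate} not in design (1..{self.n_plates})")
        r, c = divmod(plate - 1, self.g_cols)
        return (f"H{r + 1}", f"V{c + 1}")


@dataclass(frozen=True)
class SinglePlateDesign:
    """Overlapping row/column pools of one plate.

    ``row_pools`` maps pool ID (``R1``..``R8``) to its member row letters;
    ``row_pairs`` maps each row letter to its unordered pool pair.  Columns
    likewise (``C1``..``C10``).  Pair maps are injective, which is what
    makes the double-positive pattern decodable.
    """

    plate_format: PlateFormat
    row_pools: dict[str, tuple[str, ...]]
    col_pools: dict[str, tuple[int, ...]]
    row_pairs: dict[str, frozenset[str]]
    col_pairs: dict[int, frozenset[str]]

    @property
    def n_pools(self) -> int:
        return len(self.row_pools) + len(self.col_pools)

    @property
    def pool_ids(self) -> list[str]:
        return list(self.row_pools) + list(self.col_pools)


@dataclass(frozen=True)
class PoolManifest:
    """Concrete pool contents with per-member aliquot volumes.

    ``members`` are well addresses (or plate IDs rendered as strings for
    plate-level pools); ``volumes_ul`` is parallel to ``members``.
    """

    pool_id: str
    tier: str  # superpool | matrix-H | matrix-V | plate-row | plate-col
    members: tuple[str, ...]
    volumes_ul: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.volumes_ul):
            raise ValueError("members and volumes must be parallel")
        if any(v <= 0 for v in self.volumes_ul):
            raise ValueError("aliquot volumes must be positive")


@dataclass
class ValidationReport:
    """List of invariant violations; empty iff the design is decodable."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)


def build_superpools(
    layout: LibraryLayout,
    max_per: int = 25,
    mode: RoundingMode = RoundingMode.STRICT_CEIL,
) -> SuperpoolDesign:
    """Assign plates to superpools in consecutive blocks of ``max_per``.

    The physical assignment always covers every plate (``ceil(N/max_per)``
    superpools); under half-up rounding ``reported_count`` is
    ``round(N/max_per)``, the convention of published reaction tables.
    """
    if max_per < 1:
        raise ValueError("max_per must be >= 1")
    n = layout.n_plates
    n_strict = math.ceil(n / max_per)
    assignment = {p: (p - 1) // max_per + 1 for p in layout.plate_ids}
    reported = max(1, mode.apply(n / max_per))
    return SuperpoolDesign(
        max_plates_per_superpool=max_per,
        assignment=assignment,
        n_superpools=n_strict,
        reported_count=reported,
    )


def build_matrix_design(n_plates_in_superpool: int, max_per: int = 25) -> MatrixDesign:
    """Near-square grid design: ``g_cols = ceil(sqrt(n))``, pools = rows + cols.

    25 plates give the canonical 5x5 grid with 10 pools; a single plate
    gives a degenerate zero-pool design flagged ``skip_stage``.
    """
    n = n_plates_in_superpool
    if not 1 <= n <= max_per:
        raise ValueError(f"superpool must hold 1..{max_per} plates, got {n}")
    if n == 1:
        return MatrixDesign(1, 1, 1, {}, {}, skip_stage=True)
    g_cols = math.ceil(math.sqrt(n))
    g_rows = math.ceil(n / g_cols)
    h_pools: dict[str, tuple[int, ...]] = {}
    v_pools: dict[str, list[int]] = {f"V{j + 1}": [] for j in range(g_cols)}
    for r in range(g_rows):
        row_plates = [p for p in range(r * g_cols + 1, min((r + 1) * g_cols, n) + 1)]
        h_pools[f"H{r + 1}"] = tuple(row_plates)
        for j, p in enumerate(row_plates):
            v_pools[f"V{j + 1}"].append(p)
    return MatrixDesign(
        n_plates=n,
        g_rows=g_rows,
        g_cols=g_cols,
        h_pools=h_pools,
        v_pools={k: tuple(v) for k, v in v_pools.items() if v},
    )


def _lex_first_pair_assignment(
    n_items: int, capacities: dict[int, int]
) -> list[tuple[int, int]]:
    """Lexicographically first set of ``n_items`` distinct pool pairs such
    that pool ``i`` is used exactly ``capacities[i]`` times.

    Depth-first over pairs in lexicographic order with capacity pruning;
    deterministic by construction.  Raises ``ValueError`` when no assignment
    exists (counting obstruction reported).
    """
    if sum(capacities.values()) != 2 * n_items:
        raise ValueError(
            f"infeasible pair assignment: total pool capacity "
            f"{sum(capacities.values())} != 2 x {n_items} memberships"
        )
    pairs = list(combinations(sorted(capacities), 2))
    chosen: list[tuple[int, int]] = []
    used = {p: 0 for p in capacities}

    def backtrack(start: int) -> bool:
        if len(chosen) == n_items:
            return all(used[p] == capacities[p] for p in capacities)
        # not enough remaining pairs to finish
        if len(pairs) - start < n_items - len(chosen):
            return False
        for i in range(start, len(pairs)):
            a, b = pairs[i]
            if used[a] < capacities[a] and used[b] < capacities[b]:
                chosen.append(pairs[i])
                used[a] += 1
                used[b] += 1
                if backtrack(i + 1):
                    return True
                chosen.pop()
                used[a] -= 1
                used[b] -= 1
        return False

    if not backtrack(0):
        raise ValueError(
            "infeasible pair assignment: no set of distinct pairs meets the "
            "requested pool-size profile"
        )
    return chosen


def build_single_plate_design(
    plate_format: PlateFormat | None = None,
) -> SinglePlateDesign:
    """Canonical overlapping row/column pool design for one plate.

    For the default 16x24 format: 8 row pools of 4 rows each (rows in
    exactly 2 pools, all 16 pairs distinct) and 10 column pools — 6 of 4
    columns and 4 of 6 columns (columns in exactly 2 pools, all 24 pairs
    distinct), 18 pools in total.  The pair assignment is the
    lexicographically first feasible one, hence reproducible.
    """
    fmt = plate_format or PlateFormat()
    # size profiles scale only for the default-shaped format; other shapes
    # must still satisfy sum(sizes) == 2 * n_items
    if fmt.n_rows != 16 or fmt.n_cols != 24:
        raise ValueError(
            "canonical single-plate design is defined for the 16x24 format; "
            f"got {fmt.n_rows}x{fmt.n_cols} (no 2-regular pair assignment "
            "with the canonical 8-row-pool / 10-column-pool size profile)"
        )
    row_caps = {i: 4 for i in range(1, 9)}
    col_caps = {**{i: 4 for i in range(1, 7)}, **{i: 6 for i in range(7, 11)}}
    row_pair_list = _lex_first_pair_assignment(fmt.n_rows, row_caps)
    col_pair_list = _lex_first_pair_assignment(fmt.n_cols, col_caps)

    row_pairs = {
        row: frozenset({f"R{a}", f"R{b}"})
        for row, (a, b) in zip(fmt.row_labels, row_pair_list)
    }
    col_pairs = {
        col: frozenset({f"C{a}", f"C{b}"})
        for col, (a, b) in zip(fmt.col_labels, col_pair_list)
    }
    row_pools: dict[str, list[str]] = {f"R{i}": [] for i in row_caps}
    for row, pair in row_pairs.items():
        for pid in pair:
            row_pools[pid].append(row)
    col_pools: dict[str, list[int]] = {f"C{i}": [] for i in col_caps}
    for col, pair in col_pairs.items():
        for pid in pair:
            col_pools[pid].append(col)
    return SinglePlateDesign(
        plate_format=fmt,
        row_pools={k: tuple(sorted(v)) for k, v in row_pools.items()},
        col_pools={k: tuple(sorted(v)) for k, v in col_pools.items()},
        row_pairs=row_pairs,
        col_pairs=col_pairs,
    )


def validate_design(
    design: SuperpoolDesign | MatrixDesign | SinglePlateDesign,
) -> ValidationReport:
    """Check every structural invariant of a design; reports, never raises."""
    report = ValidationReport()
    if isinstance(design, SuperpoolDesign):
        _validate_superpool(design, report)
    elif isinstance(design, MatrixDesign):
        _validate_matrix(design, report)
    elif isinstance(design, SinglePlateDesign):
        _validate_single_plate(design, report)
    else:  # pragma: no cover - defensive
        report.add(f"unknown design type {type(design).__name__}")
    return report


def _validate_superpool(design: SuperpoolDesign, report: ValidationReport) -> None:
    sizes: dict[int, int] = {}
    for plate, sp in design.assignment.items():
        sizes[sp] = sizes.get(sp, 0) + 1
    for sp, size in sizes.items():
        if size > design.max_plates_per_superpool:
            report.add(
                f"superpool {sp} holds {size} plates "
                f"(max {design.max_plates_per_superpool})"
            )
    if set(sizes) != set(design.superpool_ids):
        report.add("superpool IDs are not consecutive 1..n_superpools")


def _validate_matrix(design: MatrixDesign, report: ValidationReport) -> None:
    if design.skip_stage:
        if design.h_pools or design.v_pools:
            report.add("degenerate design must have no pools")
        return
    seen_h: dict[int, str] = {}
    seen_v: dict[int, str] = {}
    for pid, plates in design.h_pools.items():
        for p in plates:
            if p in seen_h:
                report.add(f"plate {p} in both {seen_h[p]} and {pid}")
            seen_h[p] = pid
    for pid, plates in design.v_pools.items():
        for p in plates:
            if p in seen_v:
                report.add(f"plate {p} in both {seen_v[p]} and {pid}")
            seen_v[p] = pid
    for p in range(1, design.n_plates + 1):
        if p not in seen_h:
            report.add(f"plate {p} missing from horizontal pools")
        if p not in seen_v:
            report.add(f"plate {p} missing from vertical pools")
    pairs = [(seen_h.get(p), seen_v.get(p)) for p in range(1, design.n_plates + 1)]
    if len(set(pairs)) != design.n_plates:
        report.add("plate -> (H, V) map is not injective")


def _validate_single_plate(design: SinglePlateDesign, report: ValidationReport) -> None:
    fmt = design.plate_format
    for label, pairs, pools, expected_profile, n_items in (
        ("row", design.row_pairs, design.row_pools, {4: 8}, fmt.n_rows),
        ("column", design.col_pairs, design.col_pools, {4: 6, 6: 4}, fmt.n_cols),
    ):
        for item, pair in pairs.items():
            if len(pair) != 2:
                report.add(f"{label} {item} is in {len(pair)} pools, expected 2")
            for pid in pair:
                if item not in pools.get(pid, ()):
                    report.add(f"{label} {item} claims pool {pid} but pool lacks it")
        if len(set(pairs.values())) != n_items:
            dupes = [i for i in pairs if list(pairs.values()).count(pairs[i]) > 1]
            report.add(f"duplicate {label} pool-pairs for {sorted(map(str, dupes))}")
        profile: dict[int, int] = {}
        for pid, members in pools.items():
            profile[len(members)] = profile.get(len(members), 0) + 1
        if profile != expected_profile:
            report.add(
                f"{label} pool size profile {profile} != expected {expected_profile}"
            )
        total = sum(len(m) for m in pools.values())
        if total != 2 * n_items:
            report.add(f"{label} memberships sum to {total}, expected {2 * n_items}")


def pool_volume(manifest: PoolManifest) -> float:
    """Total pool volume in microlitres (sum of member aliquots).

    A full 25-plate superpool at 5 uL per clone is 5 x 25 x 384 = 48,000 uL
    (48 mL).
    """
    return float(sum(manifest.volumes_ul))


def _plate_wells(plate: int, fmt: PlateFormat) -> list[str]:
    from bacscreen.library_model import format_well_address

    return [
        format_well_address(WellAddress(row=r, column=c, plate=plate))
        for r in fmt.row_labels
        for c in fmt.col_labels
    ]


def superpool_manifest(
    superpool_id: int,
    plates: list[int],
    fmt: PlateFormat | None = None,
    aliquot_ul: float = DEFAULT_ALIQUOT_UL,
) -> PoolManifest:
    """Manifest of every clone aliquot in one superpool."""
    fmt = fmt or PlateFormat()
    members = [w for p in plates for w in _plate_wells(p, fmt)]
    return PoolManifest(
        pool_id=f"SP{superpool_id}",
        tier="superpool",
        members=tuple(members),
        volumes_ul=tuple([aliquot_ul] * len(members)),
    )


def matrix_pool_manifests(
    design: MatrixDesign,
    plate_ids: list[int] | None = None,
    fmt: PlateFormat | None = None,
    aliquot_ul: float = DEFAULT_ALIQUOT_UL,
) -> list[PoolManifest]:
    """Manifests of every matrix pool (all wells of the member plates).

    ``plate_ids`` maps within-superpool plate numbers 1..n to library plate
    IDs; identity when omitted.
    """
    fmt = fmt or PlateFormat()
    ids = plate_ids or list(range(1, design.n_plates + 1))
    out = []
    for tier, pools in (("matrix-H", design.h_pools), ("matrix-V", design.v_pools)):
        for pid, plates in pools.items():
            members = [w for p in plates for w in _plate_wells(ids[p - 1], fmt)]
            out.append(
                PoolManifest(
                    pool_id=pid,
                    tier=tier,
                    members=tuple(members),
                    volumes_ul=tuple([aliquot_ul] * len(members)),
                )
            )
    return out


def single_plate_manifests(
    design: SinglePlateDesign,
    plate: int | None = None,
    aliquot_ul: float = DEFAULT_ALIQUOT_UL,
) -> list[PoolManifest]:
    """Manifests of the 18 row/column pools of one plate."""
    from bacscreen.library_model import format_well_address

    fmt = design.plate_format
    out = []
    for pid, rows in design.row_pools.items():
        members = [
            format_well_address(WellAddress(row=r, column=c, plate=plate))
            for r in rows
            for c in fmt.col_labels
        ]
        out.append(
            PoolManifest(
                pool_id=pid,
                tier="plate-row",
                members=tuple(members),
                volumes_ul=tuple([aliquot_ul] * len(members)),
            )
        )
    for pid, cols in design.col_pools.items():
        members = [
            format_well_address(WellAddress(row=r, column=c, plate=plate))
            for c in cols
            for r in fmt.row_labels
        ]
        out.append(
            PoolManifest(
                pool_id=pid,
                tier="plate-col",
                members=tuple(members),
                volumes_ul=tuple([aliquot_ul] * len(members)),
            )
        )
    return out
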