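"""Monte-Carlo simulation of the full pooled screen on synthetic libraries.

The generator emulates the wet-lab setting the screen was designed for: a
clone library tiling a linear genome at ~3x coverage with ~100 kb inserts
stored in 384-well plates, and rare single-locus markers (a handful of
positive clones among thousands of negatives per superpool).  Clone start
positions are i.i.d. uniform on the genome; inserts are clipped at the
genome end.  A pool's true state is positive iff it contains at least one
clone carrying the marker; observed calls flip true positives to negative
with probability beta (false-negative rate) and true negatives to positive
with probability alpha (false-positive rate), independently per (pool,
marker).  Screening is gated top-down exactly as in the lab: only pools
descending from positive parents are tested, and a marker whose superpool
call is falsely negative is lost — there is no global retest.

Reaction accounting mirrors the multiplexed workflow: markers are grouped
up to 3 per reaction, the superpool and matrix stages are shared across
the markers of a group, and each candidate plate is screened with the
18-pool single-plate design per marker group present on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from bacscreen.decoder import (
    Call,
    DecodedCandidate,
    DecodeStatus,
    PoolResult,
    StageResults,
    decode_full,
    decode_matrix,
)
from bacscreen.library_model import (
    LibraryLayout,
    PlateFormat,
    WellAddress,
    paper_round,
)
from bacscreen.pooling_design import (
    MatrixDesign,
    PoolManifest,
    SinglePlateDesign,
    SuperpoolDesign,
    build_matrix_design,
    build_single_plate_design,
    build_superpools,
)
from bacscreen.reaction_calculator import MAX_MULTIPLEX

__all__ = [
    "SimConfig",
    "SimulatedLibrary",
    "ScreenOutcome",
    "PerformanceReport",
    "simulate_library",
    "build_spiked_superpool",
    "run_screen",
    "evaluate",
    "replicate_screens",
    "SPIKED_DEFAULT_NEGATIVES",
]

SPIKED_DEFAULT_NEGATIVES = (25 * 384) // 3  # 3200


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-library and screen parameters.

    Either ``coverage`` or ``n_clones`` sizes the library.  The insert
    length distribution is ``fixed`` (every insert ``insert_mean``),
    ``uniform`` (``insert_mean +/- insert_spread``) or ``normal``
    (sd ``insert_spread``, truncated at 1 bp).  Markers are point loci:
    explicit positions, or ``n_markers`` drawn uniformly.  ``alpha`` and
    ``beta`` are the per-(pool, marker) false-positive and false-negative
    call rates.
    """

    genome_size: int
    coverage: float | None = 3.0
    n_clones: int | None = None
    insert_dist: str = "fixed"  # fixed | uniform | normal
    insert_mean: int = 100_000
    insert_spread: int = 0
    marker_positions: tuple[int, ...] | None = None
    n_markers: int = 1
    alpha: float = 0.0
    beta: float = 0.0
    aliquot_ul: float = 5.0
    max_plates_per_superpool: int = 25
    n_plates: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size < 1:
            raise ValueError("genome_size must be >= 1")
        if (self.coverage is None) == (self.n_clones is None):
            raise ValueError("exactly one of coverage / n_clones must be set")
        if not 0.0 <= self.alpha < 1.0 or not 0.0 <= self.beta <= 1.0:
            raise ValueError("alpha must be in [0,1), beta in [0,1]")
        if self.insert_dist not in ("fixed", "uniform", "normal"):
            raise ValueError(f"unknown insert_dist {self.insert_dist!r}")
        if self.marker_positions is not None:
            for p in self.marker_positions:
                if not 0 <= p < self.genome_size:
                    raise ValueError(f"marker position {p} outside genome")


@dataclass(frozen=True)
class Clone:
    index: int
    address: WellAddress
    start: int
    length: int  # effective (clipped) insert length


@dataclass(frozen=True)
class SimulatedLibrary:
    """Synthetic library with ground truth marker -> clone containment."""

    config: SimConfig
    layout: LibraryLayout
    clones: tuple[Clone, ...]
    markers: dict[str, int]  # marker ID -> genomic position
    truth: dict[str, frozenset[int]]  # marker ID -> clone indices

    def truth_addresses(self, marker_id: str) -> set[WellAddress]:
        return {self.clones[i].address for i in self.truth[marker_id]}


def _clone_address(index: int, fmt: PlateFormat) -> WellAddress:
    plate, within = divmod(index, fmt.wells)
    r, c = divmod(within, fmt.n_cols)
    return WellAddress(row=fmt.row_labels[r], column=c + 1, plate=plate + 1)


def simulate_library(config: SimConfig) -> SimulatedLibrary:
    """Draw a synthetic library; bit-identical under a fixed config/seed."""
    rng = np.random.default_rng(config.seed)
    fmt = PlateFormat()
    if config.n_clones is not None:
        n_clones = config.n_clones
    else:
        n_clones = paper_round(
            config.coverage * config.genome_size / config.insert_mean
        )
    if n_clones < 1:
        raise ValueError("library would hold no clones")
    n_plates = config.n_plates or math.ceil(n_clones / fmt.wells)
    if n_clones > n_plates * fmt.wells:
        raise ValueError(
            f"{n_clones} clones exceed {n_plates} plates x {fmt.wells} wells"
        )
    starts = rng.integers(0, config.genome_size, size=n_clones)
    if config.insert_dist == "fixed":
        lengths = np.full(n_clones, config.insert_mean)
    elif config.insert_dist == "uniform":
        lengths = rng.integers(
            max(1, config.insert_mean - config.insert_spread),
            config.insert_mean + config.insert_spread + 1,
            size=n_clones,
        )
    else:  # normal
        lengths = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_spread, n_clones)),
            1, None,
        ).astype(int)
    # linear genome: clip inserts at the right end
    lengths = np.minimum(lengths, config.genome_size - starts)

    if config.marker_positions is not None:
        positions = list(config.marker_positions)
    else:
        positions = sorted(
            int(p) for p in rng.integers(0, config.genome_size, config.n_markers)
        )
    markers = {f"M{i + 1}": pos for i, pos in enumerate(positions)}

    clones = tuple(
        Clone(index=i, address=_clone_address(i, fmt),
              start=int(starts[i]), length=int(lengths[i]))
        for i in range(n_clones)
    )
    truth = {
        mid: frozenset(
            np.flatnonzero((starts <= pos) & (pos < starts + lengths)).tolist()
        )
        for mid, pos in markers.items()
    }
    layout = LibraryLayout(n_plates=n_plates, plate_format=fmt)
    return SimulatedLibrary(config=config, layout=layout, clones=clones,
                            markers=markers, truth=truth)


def build_spiked_superpool(
    n_negatives: int = SPIKED_DEFAULT_NEGATIVES,
    positive_clone: str = "P1-A1",
    positive_ul: float = 5.0,
    negative_ul: float = 15.0,
) -> PoolManifest:
    """Rare-single-locus sensitivity fixture: one positive clone at 5 uL
    spiked into a superpool of negative clones at 15 uL each.

    The default 3200 negatives ((25 x 384) / 3) emulate the dilution a
    single-copy target experiences in a full 25-plate superpool of a 3x
    library, giving a total volume of 48,005 uL.
    """
    if n_negatives < 0:
        raise ValueError("n_negatives must be >= 0")
    members = [positive_clone] + [f"NEG{i + 1}" for i in range(n_negatives)]
    volumes = [positive_ul] + [negative_ul] * n_negatives
    return PoolManifest(
        pool_id="SP-spiked",
        tier="superpool",
        members=tuple(members),
        volumes_ul=tuple(volumes),
    )


@dataclass
class ScreenOutcome:
    """Observed calls, decoded candidates and reactions consumed."""

    stage_results: dict[str, StageResults]
    decoded: dict[str, DecodedCandidate]
    reactions: dict[str, int] = field(default_factory=dict)

    @property
    def total_reactions(self) -> int:
        return sum(self.reactions.values())


def _observe(true_positive: bool, alpha: float, beta: float,
             rng: np.random.Generator) -> Call:
    if true_positive:
        return Call.NEGATIVE if rng.random() < beta else Call.POSITIVE
    return Call.POSITIVE if rng.random() < alpha else Call.NEGATIVE


def _marker_groups(markers: list[str], size: int = MAX_MULTIPLEX) -> list[list[str]]:
    return [markers[i:i + size] for i in range(0, len(markers), size)]


def run_screen(
    library: SimulatedLibrary,
    seed: int | None = None,
    tolerant: bool = False,
) -> ScreenOutcome:
    """Run the gated three-stage screen and decode every marker.

    ``seed`` drives the call-noise stream (defaults to the library config
    seed offset by 1, so library and screen noise are independent).
    """
    cfg = library.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    fmt = library.layout.plate_format
    sp_design = build_superpools(library.layout, cfg.max_plates_per_superpool)
    matrix_designs = {
        sp: build_matrix_design(len(sp_design.plates_in(sp)),
                                cfg.max_plates_per_superpool)
        for sp in sp_design.superpool_ids
    }
    plate_design = build_single_plate_design(fmt)

    # per-marker truth at each granularity
    marker_ids = list(library.markers)
    plate_of = {sp: sp_design.plates_in(sp) for sp in sp_design.superpool_ids}
    truth_plates = {
        m: {library.clones[i].address.plate for i in library.truth[m]}
        for m in marker_ids
    }
    truth_wells = {
        m: {(library.clones[i].address.plate, library.clones[i].address.row,
             library.clones[i].address.column) for i in library.truth[m]}
        for m in marker_ids
    }

    results = {m: StageResults(marker_id=m) for m in marker_ids}
    reactions = {"superpool": 0, "matrix": 0, "single_plate": 0}
    groups = _marker_groups(marker_ids)

    # --- superpool stage (skipped for a single-superpool library) ---
    pos_superpools: dict[str, list[int]] = {m: [] for m in marker_ids}
    if sp_design.n_superpools > 1:
        for group in groups:
            for sp in sp_design.superpool_ids:
                reactions["superpool"] += 1
                plates = set(plate_of[sp])
                for m in group:
                    truly = bool(truth_plates[m] & plates)
                    call = _observe(truly, cfg.alpha, cfg.beta, rng)
                    results[m].superpool.append(
                        PoolResult(f"SP{sp}", m, call)
                    )
                    if call is Call.POSITIVE:
                        pos_superpools[m].append(sp)
    else:
        for m in marker_ids:
            pos_superpools[m] = [1]

    # --- matrix stage: 10 pools per superpool positive for >=1 group marker ---
    for group in groups:
        sps = sorted({sp for m in group for sp in pos_superpools[m]})
        for sp in sps:
            design = matrix_designs[sp]
            if design.skip_stage:
                continue
            reactions["matrix"] += design.n_pools
            plates = plate_of[sp]
            for pool_id in design.pool_ids:
                pools = design.h_pools if pool_id.startswith("H") else design.v_pools
                member_plates = {plates[p - 1] for p in pools[pool_id]}
                for m in group:
                    if sp not in pos_superpools[m]:
                        continue
                    truly = bool(truth_plates[m] & member_plates)
                    call = _observe(truly, cfg.alpha, cfg.beta, rng)
                    results[m].matrix.setdefault(sp, []).append(
                        PoolResult(pool_id, m, call)
                    )

    # --- single-plate stage: decode matrix to candidate plates first ---
    candidate_plates: dict[str, list[int]] = {}
    for m in marker_ids:
        plates: list[int] = []
        for sp in pos_superpools[m]:
            design = matrix_designs[sp]
            if design.skip_stage:
                plates.extend(plate_of[sp])
                continue
            if sp not in results[m].matrix:
                continue
            dec = decode_matrix(results[m].matrix[sp], design)
            plates.extend(plate_of[sp][p - 1] for p in dec.candidates)
        candidate_plates[m] = sorted(set(plates))

    plate_markers: dict[int, list[str]] = {}
    for m, plates in candidate_plates.items():
        for p in plates:
            plate_markers.setdefault(p, []).append(m)
    for plate_id in sorted(plate_markers):
        for group in _marker_groups(plate_markers[plate_id]):
            reactions["single_plate"] += plate_design.n_pools
            for pool_id in plate_design.pool_ids:
                if pool_id.startswith("R"):
                    rows = set(plate_design.row_pools[pool_id])
                    member = lambda w: w[1] in rows  # noqa: E731
                else:
                    cols = set(plate_design.col_pools[pool_id])
                    member = lambda w: w[2] in cols  # noqa: E731
                for m in group:
                    truly = any(
                        w[0] == plate_id and member(w) for w in truth_wells[m]
                    )
                    call = _observe(truly, cfg.alpha, cfg.beta, rng)
                    results[m].plate.setdefault(plate_id, []).append(
                        PoolResult(pool_id, m, call)
                    )

    decoded = {
        m: decode_full(results[m], sp_design, matrix_designs, plate_design,
                       tolerant=tolerant)
        for m in marker_ids
    }
    return ScreenOutcome(stage_results=results, decoded=decoded,
                         reactions=reactions)


@dataclass
class PerformanceReport:
    """Recovery quality of one or more screens against ground truth."""

    per_marker: dict[str, dict[str, float]]
    sensitivity: float
    phantom_rate: float
    ambiguity_rate: float
    n_replicates: int = 1
    sensitivity_sd: float = 0.0


def evaluate(outcome: ScreenOutcome, library: SimulatedLibrary) -> PerformanceReport:
    """Score decoded addresses against the library's truth map.

    Sensitivity is the fraction of true marker-carrying clones whose
    address appears among the decoded candidates; phantom addresses
    (reported but not true) are counted separately; the ambiguity rate is
    the fraction of markers not decoded to a unique address.
    """
    per_marker: dict[str, dict[str, float]] = {}
    tp = fn = phantoms = ambiguous = 0
    for m, dec in outcome.decoded.items():
        truth = library.truth_addresses(m)
        found = {
            (a.plate, a.row, a.column) for a in dec.candidates
        }
        truth_keys = {(a.plate, a.row, a.column) for a in truth}
        m_tp = len(found & truth_keys)
        m_fn = len(truth_keys - found)
        m_ph = len(found - truth_keys)
        is_amb = dec.status not in (DecodeStatus.UNIQUE, DecodeStatus.UNIQUE_NEGATIVE)
        per_marker[m] = {
            "true_clones": len(truth_keys),
            "recovered": m_tp,
            "missed": m_fn,
            "phantoms": m_ph,
            "unique": float(dec.status is DecodeStatus.UNIQUE),
        }
        tp += m_tp
        fn += m_fn
        phantoms += m_ph
        ambiguous += is_amb
    n_truth = tp + fn
    n_markers = max(len(outcome.decoded), 1)
    return PerformanceReport(
        per_marker=per_marker,
        sensitivity=tp / n_truth if n_truth else 1.0,
        phantom_rate=phantoms / n_markers,
        ambiguity_rate=ambiguous / n_markers,
    )


def replicate_screens(
    config: SimConfig, seeds: list[int], tolerant: bool = False
) -> PerformanceReport:
    """Aggregate recovery over independent replicate screens.

    Each seed regenerates the library (seeded by the replicate seed) and
    the call noise, so replicates are fully independent.
    """
    sens, phant, amb = [], [], []
    per_marker_last: dict[str, dict[str, float]] = {}
    for s in seeds:
        lib = simulate_library(replace(config, seed=int(s)))
        rep = evaluate(run_screen(lib, seed=int(s) + 10_000_019), lib)
        sens.append(rep.sensitivity)
        phant.append(rep.phantom_rate)
        amb.append(rep.ambiguity_rate)
        per_marker_last = rep.per_marker
    return PerformanceReport(
        per_marker=per_marker_last,
        sensitivity=float(np.mean(sens)),
        phantom_rate=float(np.mean(phant)),
        ambiguity_rate=float(np.mean(amb)),
        n_replicates=len(seeds),
        sensitivity_sd=float(np.std(sens, ddof=1)) if len(seeds) > 1 else 0.0,
    )
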