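"""Decode positive/negative pool calls back to plates and wells.

Decoding inverts the pooling encode: a single positive plate produces
exactly one positive H and one positive V matrix pool, and a single
positive well produces exactly two positive row pools and two positive
column pools whose pairs are unique to its row and column.  With more
positives than a single target explains, the decoder reports the full set
of consistent candidates (flagged ``ambiguous``) rather than guessing —
overlap pair designs are not 2-disjunct, so two simultaneous positives can
produce phantom candidate combinations, and those are reported too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from bacscreen.library_model import WellAddress
from bacscreen.pooling_design import (
    MatrixDesign,
    SinglePlateDesign,
    SuperpoolDesign,
)

__all__ = [
    "Call",
    "PoolResult",
    "DecodeStatus",
    "DecodedCandidate",
    "StageResults",
    "decode_superpools",
    "decode_matrix",
    "decode_single_plate",
    "decode_full",
]


class Call(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class PoolResult:
    """One observed call for one pool and one marker."""

    pool_id: str
    marker_id: str
    call: Call
    note: str = ""


class DecodeStatus(str, Enum):
    UNIQUE = "unique"            # exactly one candidate
    UNIQUE_NEGATIVE = "unique-negative"  # all pools negative, empty set
    AMBIGUOUS = "ambiguous"      # >1 consistent candidate
    INCONSISTENT = "inconsistent"  # pattern matches no target
    INCONSISTENT_TOLERATED = "inconsistent-tolerated"  # salvaged under tolerant mode


@dataclass
class DecodedCandidate:
    """Decoder output for one marker at one stage."""

    marker_id: str
    candidates: list = field(default_factory=list)
    status: DecodeStatus = DecodeStatus.UNIQUE_NEGATIVE
    explanation: str = ""


def _positives(results: list[PoolResult], known: set[str], stage: str) -> set[str]:
    for r in results:
        if r.pool_id not in known:
            raise ValueError(f"unknown pool {r.pool_id!r} in {stage} results")
    return {r.pool_id for r in results if r.call is Call.POSITIVE}


def decode_superpools(
    results: list[PoolResult], design: SuperpoolDesign
) -> DecodedCandidate:
    """Positive superpool IDs straight from the calls (one pool per superpool)."""
    marker = results[0].marker_id if results else ""
    known = {f"SP{i}" for i in design.superpool_ids}
    pos = sorted(_positives(results, known, "superpool"))
    ids = [int(p[2:]) for p in pos]
    if not ids:
        return DecodedCandidate(marker, [], DecodeStatus.UNIQUE_NEGATIVE,
                                "no positive superpool")
    status = DecodeStatus.UNIQUE if len(ids) == 1 else DecodeStatus.AMBIGUOUS
    return DecodedCandidate(marker, ids, status, f"positive superpools {ids}")


def decode_matrix(results: list[PoolResult], design: MatrixDesign) -> DecodedCandidate:
    """Intersect positive H and V pools to candidate plates.

    One positive per dimension gives the unique plate; ``h x v`` positives
    give the ambiguous intersection set; positives in only one dimension
    are inconsistent (every true plate lights both its pools).
    """
    marker = results[0].marker_id if results else ""
    known = set(design.pool_ids)
    pos = _positives(results, known, "matrix")
    pos_h = sorted(p for p in pos if p.startswith("H"))
    pos_v = sorted(p for p in pos if p.startswith("V"))
    if not pos_h and not pos_v:
        return DecodedCandidate(marker, [], DecodeStatus.UNIQUE_NEGATIVE,
                                "all matrix pools negative")
    if not pos_h or not pos_v:
        missing = "horizontal" if not pos_h else "vertical"
        return DecodedCandidate(
            marker, [], DecodeStatus.INCONSISTENT,
            f"positives in one dimension only ({missing} pools all negative)",
        )
    plates = sorted(
        p
        for p in range(1, design.n_plates + 1)
        if design.membership(p)[0] in pos_h and design.membership(p)[1] in pos_v
    )
    if not plates:
        return DecodedCandidate(marker, [], DecodeStatus.INCONSISTENT,
                                "positive pools intersect at no plate")
    if len(plates) == 1:
        return DecodedCandidate(
            marker, plates, DecodeStatus.UNIQUE,
            f"plate {plates[0]} at intersection of {pos_h[0]} and {pos_v[0]}",
        )
    return DecodedCandidate(
        marker, plates, DecodeStatus.AMBIGUOUS,
        f"{len(pos_h)} positive H x {len(pos_v)} positive V pools give "
        f"{len(plates)} candidate plates",
    )


def decode_single_plate(
    results: list[PoolResult],
    design: SinglePlateDesign,
    tolerant: bool = False,
    plate: int | None = None,
) -> DecodedCandidate:
    """Map positive row/column pool pairs to candidate wells.

    Candidates are every well whose row pair and column pair are both
    subsets of the positives (the union-of-patterns interpretation: with
    multiple true positives this can include phantom pair combinations,
    which are reported, not suppressed).  Under ``tolerant`` mode a single
    positive pool in a dimension — one false negative away from a valid
    pair — expands to that pool's members instead of failing.
    """
    marker = results[0].marker_id if results else ""
    known = set(design.pool_ids)
    pos = _positives(results, known, "single-plate")
    pos_r = {p for p in pos if p.startswith("R")}
    pos_c = {p for p in pos if p.startswith("C")}
    if not pos_r and not pos_c:
        return DecodedCandidate(marker, [], DecodeStatus.UNIQUE_NEGATIVE,
                                "all single-plate pools negative")

    cand_rows = [r for r, pair in design.row_pairs.items() if pair <= pos_r]
    cand_cols = [c for c, pair in design.col_pairs.items() if pair <= pos_c]
    tolerated = False
    if tolerant:
        if not cand_rows and len(pos_r) == 1:
            cand_rows = list(design.row_pools[next(iter(pos_r))])
            tolerated = True
        if not cand_cols and len(pos_c) == 1:
            cand_cols = list(design.col_pools[next(iter(pos_c))])
            tolerated = True
    if not cand_rows or not cand_cols:
        missing = []
        if not cand_rows:
            missing.append(f"row positives {sorted(pos_r)} match no row pair")
        if not cand_cols:
            missing.append(f"column positives {sorted(pos_c)} match no column pair")
        return DecodedCandidate(marker, [], DecodeStatus.INCONSISTENT,
                                "; ".join(missing))
    wells = sorted(
        WellAddress(row=r, column=c, plate=plate)
        for r in cand_rows
        for c in cand_cols
    )
    if tolerated:
        return DecodedCandidate(
            marker, wells, DecodeStatus.INCONSISTENT_TOLERATED,
            "single positive pool in one dimension expanded to pool members "
            "(tolerant mode)",
        )
    if len(wells) == 1:
        return DecodedCandidate(marker, wells, DecodeStatus.UNIQUE,
                                f"unique well {wells[0].row}{wells[0].column}")
    return DecodedCandidate(
        marker, wells, DecodeStatus.AMBIGUOUS,
        f"{len(cand_rows)} candidate rows x {len(cand_cols)} candidate columns",
    )


@dataclass
class StageResults:
    """Observed calls for one marker across the three screening stages.

    ``superpool`` may be empty when the whole library fits one superpool
    (the stage is then skipped and every superpool is treated as positive).
    ``matrix`` is keyed by superpool ID, ``plate`` by library plate ID.
    """

    marker_id: str
    superpool: list[PoolResult] = field(default_factory=list)
    matrix: dict[int, list[PoolResult]] = field(default_factory=dict)
    plate: dict[int, list[PoolResult]] = field(default_factory=dict)


def decode_full(
    stage_results: StageResults,
    superpool_design: SuperpoolDesign,
    matrix_designs: dict[int, MatrixDesign],
    plate_design: SinglePlateDesign,
    tolerant: bool = False,
) -> DecodedCandidate:
    """Chain superpool -> matrix -> single-plate decoding for one marker.

    Returns well-level candidates with library plate IDs attached.
    Ambiguity propagates: every candidate plate of every candidate
    superpool whose stage results are supplied is decoded.  Plate-stage
    results for plates outside positive superpools are an input error.
    """
    marker = stage_results.marker_id

    if stage_results.superpool:
        sp_dec = decode_superpools(stage_results.superpool, superpool_design)
        pos_superpools = list(sp_dec.candidates)
        if not pos_superpools:
            return DecodedCandidate(marker, [], DecodeStatus.UNIQUE_NEGATIVE,
                                    "no positive superpool")
    elif superpool_design.n_superpools == 1:
        pos_superpools = [1]
    else:
        return DecodedCandidate(
            marker, [], DecodeStatus.INCONSISTENT,
            "superpool stage results required for a multi-superpool library",
        )

    candidate_plates: list[int] = []
    statuses: list[DecodeStatus] = []
    for sp in pos_superpools:
        if sp not in stage_results.matrix:
            continue
        design = matrix_designs[sp]
        plates_in_sp = superpool_design.plates_in(sp)
        if design.skip_stage:
            candidate_plates.extend(plates_in_sp)
            continue
        dec = decode_matrix(stage_results.matrix[sp], design)
        statuses.append(dec.status)
        candidate_plates.extend(plates_in_sp[p - 1] for p in dec.candidates)

    allowed = set(candidate_plates)
    for plate_id in stage_results.plate:
        if plate_id not in allowed:
            raise ValueError(
                f"plate-stage results for plate {plate_id}, which is not a "
                "candidate from the matrix stage"
            )

    wells: list[WellAddress] = []
    for plate_id in sorted(stage_results.plate):
        dec = decode_single_plate(
            stage_results.plate[plate_id], plate_design,
            tolerant=tolerant, plate=plate_id,
        )
        statuses.append(dec.status)
        wells.extend(dec.candidates)

    if any(s is DecodeStatus.INCONSISTENT for s in statuses):
        status = DecodeStatus.INCONSISTENT
    elif not wells:
        status = DecodeStatus.UNIQUE_NEGATIVE
    elif any(s is DecodeStatus.INCONSISTENT_TOLERATED for s in statuses):
        status = DecodeStatus.INCONSISTENT_TOLERATED
    elif len(wells) == 1:
        status = DecodeStatus.UNIQUE
    else:
        status = DecodeStatus.AMBIGUOUS
    return DecodedCandidate(
        marker, sorted(wells), status,
        f"{len(wells)} candidate well(s) across {len(stage_results.plate)} "
        "screened plate(s)",
    )
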