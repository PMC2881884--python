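"""Decoder tests, anchored on a brute-force encode oracle.

The oracle enumerates, for a hypothesized set of true targets, the exact
pool pattern they would produce, and decoding must return a candidate set
containing the truth (exactly the truth for a single target).
"""

import pytest

from bacscreen.decoder import (
    Call,
    DecodeStatus,
    PoolResult,
    StageResults,
    decode_full,
    decode_matrix,
    decode_single_plate,
)
from bacscreen.library_model import LibraryLayout
from bacscreen.pooling_design import build_superpools


def encode_matrix(design, plates):
    """Oracle: calls every matrix pool positive iff it holds a true plate."""
    positive = set()
    for p in plates:
        h, v = design.membership(p)
        positive |= {h, v}
    return [
        PoolResult(pid, "M", Call.POSITIVE if pid in positive else Call.NEGATIVE)
        for pid in design.pool_ids
    ]


def encode_plate(design, wells, drop_pools=()):
    """Oracle: single-plate pool pattern for true wells (row, col) tuples."""
    positive = set()
    for row, col in wells:
        positive |= design.row_pairs[row] | design.col_pairs[col]
    positive -= set(drop_pools)
    return [
        PoolResult(pid, "M", Call.POSITIVE if pid in positive else Call.NEGATIVE)
        for pid in design.pool_ids
    ]


class TestMatrixDecoding:
    def test_single_positive_plate_recovered_exactly_all_positions(self, matrix25):
        for plate in range(1, 26):
            dec = decode_matrix(encode_matrix(matrix25, [plate]), matrix25)
            assert dec.status is DecodeStatus.UNIQUE
            assert dec.candidates == [plate]

    def test_figure_worked_example_h5_v3_is_plate_23(self, matrix25):
        results = [
            PoolResult(pid, "M",
                       Call.POSITIVE if pid in ("H5", "V3") else Call.NEGATIVE)
            for pid in matrix25.pool_ids
        ]
        dec = decode_matrix(results, matrix25)
        assert dec.candidates == [23]

    def test_all_negative_is_clean_empty(self, matrix25):
        dec = decode_matrix(encode_matrix(matrix25, []), matrix25)
        assert dec.status is DecodeStatus.UNIQUE_NEGATIVE
        assert dec.candidates == []

    def test_two_by_two_positives_give_four_ambiguous_plates(self, matrix25):
        results = [
            PoolResult(pid, "M",
                       Call.POSITIVE if pid in ("H1", "H2", "V1", "V2")
                       else Call.NEGATIVE)
            for pid in matrix25.pool_ids
        ]
        dec = decode_matrix(results, matrix25)
        assert dec.status is DecodeStatus.AMBIGUOUS
        assert dec.candidates == [1, 2, 6, 7]

    def test_one_dimension_only_is_inconsistent(self, matrix25):
        results = [
            PoolResult(pid, "M",
                       Call.POSITIVE if pid == "H1" else Call.NEGATIVE)
            for pid in matrix25.pool_ids
        ]
        assert decode_matrix(results, matrix25).status is DecodeStatus.INCONSISTENT

    def test_unknown_pool_rejected(self, matrix25):
        with pytest.raises(ValueError, match="unknown pool"):
            decode_matrix([PoolResult("H9", "M", Call.POSITIVE)], matrix25)


class TestSinglePlateDecoding:
    def test_every_well_round_trips_exactly(self, plate_design):
        fmt = plate_design.plate_format
        for row in fmt.row_labels:
            for col in fmt.col_labels:
                dec = decode_single_plate(
                    encode_plate(plate_design, [(row, col)]), plate_design
                )
                assert dec.status is DecodeStatus.UNIQUE
                assert [(a.row, a.column) for a in dec.candidates] == [(row, col)]

    def test_all_negative_is_empty(self, plate_design):
        dec = decode_single_plate(encode_plate(plate_design, []), plate_design)
        assert dec.status is DecodeStatus.UNIQUE_NEGATIVE

    def test_two_true_wells_both_contained_in_candidates(self, plate_design):
        wells = [("D", 13), ("A", 1)]
        dec = decode_single_plate(encode_plate(plate_design, wells), plate_design)
        got = {(a.row, a.column) for a in dec.candidates}
        assert set(wells) <= got  # truth contained; phantoms permitted
        # brute-force oracle: every well whose pairs are subsets of positives
        positives = {
            pid for w in wells
            for pid in plate_design.row_pairs[w[0]] | plate_design.col_pairs[w[1]]
        }
        expect = {
            (r, c)
            for r in plate_design.plate_format.row_labels
            for c in plate_design.plate_format.col_labels
            if plate_design.row_pairs[r] <= positives
            and plate_design.col_pairs[c] <= positives
        }
        assert got == expect

    def test_spurious_positive_never_shrinks_candidates(self, plate_design):
        base = encode_plate(plate_design, [("D", 13)])
        base_set = {
            (a.row, a.column)
            for a in decode_single_plate(base, plate_design).candidates
        }
        for flip in plate_design.pool_ids:
            noisy = [
                PoolResult(r.pool_id, r.marker_id,
                           Call.POSITIVE if r.pool_id == flip else r.call)
                for r in base
            ]
            got = {
                (a.row, a.column)
                for a in decode_single_plate(noisy, plate_design).candidates
            }
            assert base_set <= got

    def test_tolerant_mode_survives_one_false_negative(self, plate_design):
        # drop any single one of the 4 pools covering the well: the true well
        # must remain among the candidates in tolerant mode
        fmt = plate_design.plate_format
        for row, col in [(r, c) for r in fmt.row_labels[:4] for c in (1, 13, 24)]:
            covering = sorted(
                plate_design.row_pairs[row] | plate_design.col_pairs[col]
            )
            for dropped in covering:
                results = encode_plate(plate_design, [(row, col)],
                                       drop_pools=[dropped])
                dec = decode_single_plate(results, plate_design, tolerant=True)
                assert (row, col) in {(a.row, a.column) for a in dec.candidates}

    def test_intolerant_mode_reports_inconsistent_on_false_negative(
        self, plate_design
    ):
        covering = sorted(
            plate_design.row_pairs["D"] | plate_design.col_pairs[13]
        )
        results = encode_plate(plate_design, [("D", 13)],
                               drop_pools=[covering[0]])
        dec = decode_single_plate(results, plate_design, tolerant=False)
        assert dec.status is DecodeStatus.INCONSISTENT


class TestFullPipeline:
    def _designs(self, n_plates):
        from bacscreen.pooling_design import (
            build_matrix_design,
            build_single_plate_design,
        )

        layout = LibraryLayout(n_plates=n_plates)
        sp = build_superpools(layout)
        matrix = {
            s: build_matrix_design(len(sp.plates_in(s)))
            for s in sp.superpool_ids
        }
        return sp, matrix, build_single_plate_design()

    def test_single_superpool_library_skips_superpool_stage(self, plate_design):
        # 24-plate library: whole library in one superpool, decoding starts
        # at the matrix stage
        sp, matrix, pdesign = self._designs(24)
        target_plate, row, col = 7, "D", 13
        m_results = encode_matrix(matrix[1], [target_plate])
        p_results = encode_plate(pdesign, [(row, col)])
        sr = StageResults(marker_id="M1", matrix={1: m_results},
                          plate={target_plate: p_results})
        dec = decode_full(sr, sp, matrix, pdesign)
        assert dec.status is DecodeStatus.UNIQUE
        addr = dec.candidates[0]
        assert (addr.plate, addr.row, addr.column) == (target_plate, row, col)

    def test_multi_superpool_library_decodes_through_all_stages(self):
        sp, matrix, pdesign = self._designs(50)  # 2 superpools
        # target: plate 30 = superpool 2, plate 5 within it
        sp_results = [
            PoolResult("SP1", "M1", Call.NEGATIVE),
            PoolResult("SP2", "M1", Call.POSITIVE),
        ]
        m_results = encode_matrix(matrix[2], [5])
        p_results = encode_plate(pdesign, [("A", 1)])
        sr = StageResults(marker_id="M1", superpool=sp_results,
                          matrix={2: m_results}, plate={30: p_results})
        dec = decode_full(sr, sp, matrix, pdesign)
        assert dec.status is DecodeStatus.UNIQUE
        addr = dec.candidates[0]
        assert (addr.plate, addr.row, addr.column) == (30, "A", 1)

    def test_two_markers_on_one_plate_decode_independently(self, plate_design):
        sp, matrix, pdesign = self._designs(24)
        decs = {}
        for marker, (row, col) in {"M1": ("D", 13), "M2": ("P", 24)}.items():
            sr = StageResults(
                marker_id=marker,
                matrix={1: encode_matrix(matrix[1], [7])},
                plate={7: encode_plate(pdesign, [(row, col)])},
            )
            decs[marker] = decode_full(sr, sp, matrix, pdesign)
        assert all(d.status is DecodeStatus.UNIQUE for d in decs.values())
        assert (decs["M1"].candidates[0].row, decs["M1"].candidates[0].column) \
            == ("D", 13)
        assert (decs["M2"].candidates[0].row, decs["M2"].candidates[0].column) \
            == ("P", 24)

    def test_plate_results_outside_positive_superpools_rejected(self):
        sp, matrix, pdesign = self._designs(50)
        sr = StageResults(
            marker_id="M1",
            superpool=[PoolResult("SP1", "M1", Call.POSITIVE),
                       PoolResult("SP2", "M1", Call.NEGATIVE)],
            matrix={1: encode_matrix(matrix[1], [1])},
            plate={40: encode_plate(pdesign, [("A", 1)])},  # superpool 2!
        )
        with pytest.raises(ValueError, match="not a candidate"):
            decode_full(sr, sp, matrix, pdesign)
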