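"""CTC reading, writing and validation."""

import numpy as np
import pytest
import tifffile

from cellhota import (
    GROUND_TRUTH,
    TRACKER,
    CTCFormatError,
    ScenarioConfig,
    Sequence,
    TrackRecord,
    generate,
    read_sequence,
    validate_sequence,
    write_sequence,
)


def _write_masks(tmp_path, frames, stem="man_track"):
    for t, img in enumerate(frames):
        tifffile.imwrite(tmp_path / f"{stem}{t:03d}.tif",
                         np.asarray(img, dtype=np.uint16))


def _one_cell_frames(n=3, label=1):
    img = np.zeros((8, 8), dtype=np.uint16)
    img[2:5, 2:5] = label
    return [img] * n


class TestRead:
    def test_minimal_sequence(self, tmp_path):
        _write_masks(tmp_path, _one_cell_frames(3))
        (tmp_path / "man_track.txt").write_text("1 0 2 0\n")
        seq = read_sequence(tmp_path, tmp_path / "man_track.txt", GROUND_TRUTH)
        assert seq.n_frames == 3
        assert seq.tracks == [TrackRecord(1, 0, 2, 0)]

    def test_division_table_parse(self, tmp_path):
        base = np.zeros((8, 8), dtype=np.uint16)
        parent = base.copy(); parent[2:6, 2:5] = 1
        daughters = base.copy()
        daughters[2:4, 2:5] = 2
        daughters[4:6, 2:5] = 3
        _write_masks(tmp_path, [parent, parent, daughters, daughters])
        (tmp_path / "man_track.txt").write_text("1 0 1 0\n2 2 3 1\n3 2 3 1\n")
        seq = read_sequence(tmp_path, tmp_path / "man_track.txt", GROUND_TRUTH)
        recs = {t.label: t for t in seq.tracks}
        assert recs[2].parent == recs[3].parent == 1
        assert recs[2].begin == recs[3].begin == 2

    def test_order_insensitive_parse(self, tmp_path):
        base = np.zeros((8, 8), dtype=np.uint16)
        parent = base.copy(); parent[2:6, 2:5] = 1
        daughters = base.copy()
        daughters[2:4, 2:5] = 2
        daughters[4:6, 2:5] = 3
        _write_masks(tmp_path, [parent, daughters])
        lines = ["1 0 0 0", "2 1 1 1", "3 1 1 1"]
        (tmp_path / "a.txt").write_text("\n".join(lines) + "\n")
        (tmp_path / "b.txt").write_text("\n".join(reversed(lines)) + "\n")
        a = read_sequence(tmp_path, tmp_path / "a.txt", GROUND_TRUTH)
        b = read_sequence(tmp_path, tmp_path / "b.txt", GROUND_TRUTH)
        assert sorted(a.tracks) == sorted(b.tracks)

    def test_dangling_parent_is_an_error(self, tmp_path):
        img = np.zeros((8, 8), dtype=np.uint16)
        img[2:5, 2:5] = 2
        _write_masks(tmp_path, [img, img])
        (tmp_path / "man_track.txt").write_text("2 0 1 1\n")
        with pytest.raises(CTCFormatError, match="1"):
            read_sequence(tmp_path, tmp_path / "man_track.txt", GROUND_TRUTH)

    def test_duplicate_label_rejected(self, tmp_path):
        _write_masks(tmp_path, _one_cell_frames(2))
        (tmp_path / "man_track.txt").write_text("1 0 1 0\n1 0 1 0\n")
        with pytest.raises(CTCFormatError, match="duplicate"):
            read_sequence(tmp_path, tmp_path / "man_track.txt", GROUND_TRUTH)

    def test_noncontiguous_frames_rejected(self, tmp_path):
        frames = _one_cell_frames(2)
        tifffile.imwrite(tmp_path / "man_track000.tif", frames[0])
        tifffile.imwrite(tmp_path / "man_track002.tif", frames[1])
        (tmp_path / "man_track.txt").write_text("1 0 1 0\n")
        with pytest.raises(CTCFormatError, match="contiguous"):
            read_sequence(tmp_path, tmp_path / "man_track.txt", GROUND_TRUTH)

    def test_nonzero_start_numbering_is_normalised(self, tmp_path):
        for t, img in enumerate(_one_cell_frames(2), start=5):
            tifffile.imwrite(tmp_path / f"man_track{t:03d}.tif", img)
        (tmp_path / "man_track.txt").write_text("1 5 6 0\n")
        seq = read_sequence(tmp_path, tmp_path / "man_track.txt", GROUND_TRUTH)
        assert seq.tracks == [TrackRecord(1, 0, 1, 0)]

    def test_float_pixels_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "mask000.tif",
                         np.zeros((4, 4), dtype=np.float32))
        (tmp_path / "res_track.txt").write_text("")
        with pytest.raises(CTCFormatError, match="pixel type"):
            read_sequence(tmp_path, tmp_path / "res_track.txt", TRACKER)


class TestWrite:
    @pytest.mark.parametrize("role", [GROUND_TRUTH, TRACKER])
    def test_round_trip_is_identity(self, tmp_path, role):
        seq = generate(ScenarioConfig(
            n_initial_cells=2, n_frames=4, division_schedule=((1, 2),),
        ))
        seq.role = role
        out = write_sequence(seq, tmp_path / "seq")
        table = out / ("man_track.txt" if role == GROUND_TRUTH else "res_track.txt")
        back = read_sequence(out, table, role)
        assert np.array_equal(back.frames, seq.frames)
        assert sorted(back.tracks) == sorted(seq.tracks)
        assert back.role == role

    def test_label_above_16bit_rejected(self, tmp_path):
        img = np.zeros((4, 4), dtype=np.int64)
        img[1:3, 1:3] = 70000
        seq = Sequence(img[None], [TrackRecord(70000, 0, 0, 0)], TRACKER)
        with pytest.raises(CTCFormatError, match="16-bit"):
            write_sequence(seq, tmp_path)

    def test_empty_movie_rejected(self, tmp_path):
        seq = Sequence(np.zeros((0, 4, 4), dtype=np.int64), [], TRACKER)
        with pytest.raises(CTCFormatError, match="empty"):
            write_sequence(seq, tmp_path)


class TestValidate:
    def test_valid_sequence_has_no_diagnostics(self):
        seq = generate(ScenarioConfig(n_initial_cells=2, n_frames=3))
        assert validate_sequence(seq) == []

    def test_label_outside_track_span(self):
        img = np.zeros((6, 6), dtype=np.int64)
        img[1:3, 1:3] = 5
        frames = np.stack([img] * 5)
        seq = Sequence(frames, [TrackRecord(5, 0, 3, 0)], GROUND_TRUTH)
        diags = [d for d in validate_sequence(seq)
                 if d.kind == "label-outside-track-span"]
        assert len(diags) == 1
        assert diags[0].frame == 4 and diags[0].label == 5

    def test_single_child_parent_link_is_a_warning(self):
        img1 = np.zeros((6, 6), dtype=np.int64); img1[1:3, 1:3] = 1
        img2 = np.zeros((6, 6), dtype=np.int64); img2[1:3, 1:3] = 2
        seq = Sequence(
            np.stack([img1, img2]),
            [TrackRecord(1, 0, 0, 0), TrackRecord(2, 1, 1, 1)],
            GROUND_TRUTH,
        )
        diags = validate_sequence(seq)
        assert [d.kind for d in diags] == ["single-child-parent-link"]
        assert diags[0].severity == "warning"

    def test_three_simultaneous_daughters_rejected(self):
        img1 = np.zeros((8, 8), dtype=np.int64); img1[1:7, 1:3] = 1
        img2 = np.zeros((8, 8), dtype=np.int64)
        img2[1:3, 1:3] = 2; img2[3:5, 1:3] = 3; img2[5:7, 1:3] = 4
        seq = Sequence(
            np.stack([img1, img2]),
            [TrackRecord(1, 0, 0, 0)]
            + [TrackRecord(k, 1, 1, 1) for k in (2, 3, 4)],
            GROUND_TRUTH,
        )
        assert any(d.kind == "polytomy" and d.severity == "error"
                   for d in validate_sequence(seq))
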