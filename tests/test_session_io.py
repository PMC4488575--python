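"""Data model invariants and CSV/JSON/MIDI round trips."""

import struct

import numpy as np
import pytest

from tapentrain import (StimulusTrack, StudyDataset, TapTrial, read_trials,
                        write_trials)
from tapentrain._midi import MidiFormatError
from tapentrain.session_io import DataError, SchemaError, read_midi_onsets
from tapentrain.synthetic_data import simulate_study


class TestTapTrial:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(DataError, match="t0"):
            TapTrial(trial_id="t0", role="test",
                     onsets_ms=(0.0, 400.0, 400.0))

    def test_key_labels_must_alternate(self):
        with pytest.raises(DataError, match="alternate"):
            TapTrial(trial_id="t1", role="test",
                     onsets_ms=(0.0, 400.0, 800.0),
                     key_labels=("C4", "C4", "C5"))

    def test_completeness_threshold(self):
        trial = TapTrial(trial_id="t2", role="test",
                         onsets_ms=tuple(400.0 * i for i in range(30)))
        assert trial.is_complete()
        assert not TapTrial(trial_id="t3", role="test",
                            onsets_ms=(0.0, 400.0)).is_complete()


class TestStimulusTrack:
    def test_isochronous_interval_check(self):
        with pytest.raises(ValueError, match="nominal"):
            StimulusTrack(condition="ISI400",
                          onsets_ms=(0.0, 400.0, 850.0))

    def test_random_track_menu_check(self):
        with pytest.raises(ValueError, match="menu"):
            StimulusTrack(condition="RANDOM", onsets_ms=(0.0, 450.0))

    def test_no_stim_has_no_onsets(self):
        with pytest.raises(ValueError):
            StimulusTrack(condition="NO_STIM", onsets_ms=(0.0,))


class TestCsvRoundTrip:
    def test_single_trial_identity(self, tmp_path):
        dataset = StudyDataset(participant_id="p1")
        track = StimulusTrack(condition="ISI400",
                              onsets_ms=(0.0, 400.0, 800.0))
        trial = TapTrial(trial_id="t0", role="test",
                         onsets_ms=(0.0, 400.0, 800.0))
        dataset.sessions["ISI400"] = [(trial, track)]
        path = tmp_path / "study.csv"
        write_trials(dataset, path)
        loaded = read_trials(path)
        assert loaded.participant_id == "p1"
        assert loaded.test_trials("ISI400")[0].onsets_ms == trial.onsets_ms
        assert loaded.track_for("ISI400").onsets_ms == track.onsets_ms

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_simulated_study_round_trip_exact(self, tmp_path, fmt):
        dataset = simulate_study("human_like", seed=5,
                                 conditions=["NO_STIM", "ISI400"])
        path = tmp_path / f"study.{fmt}"
        write_trials(dataset, path, format=fmt)
        loaded = read_trials(path, format=fmt)
        for cond in dataset.sessions:
            orig = dataset.test_trials(cond)
            back = loaded.test_trials(cond)
            assert len(back) == len(orig)
            for a, b in zip(orig, back):
                assert a.onsets_ms == b.onsets_ms  # bit-identical
        assert len(loaded.training_pool) == len(dataset.training_pool)

    def test_complete_condition_has_540_rows(self, tmp_path):
        dataset = simulate_study("human_like", seed=6,
                                 conditions=["ISI400"])
        path = tmp_path / "study.csv"
        write_trials(dataset, path)
        import pandas as pd
        frame = pd.read_csv(path)
        assert (frame["condition"] == "ISI400").sum() == 540

    def test_empty_dataset_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_trials(StudyDataset(participant_id="p"), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("participant,")

    def test_duplicate_onset_is_a_data_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "participant,condition,session,trial,role,tap_index,onset_ms,key\n"
            "p,ISI400,0,t9,test,0,100.0,C4\n"
            "p,ISI400,0,t9,test,1,100.0,C5\n")
        with pytest.raises(DataError, match="t9"):
            read_trials(path)

    def test_jitter_within_tolerance_is_sorted(self, tmp_path):
        path = tmp_path / "jitter.csv"
        path.write_text(
            "participant,condition,session,trial,role,tap_index,onset_ms,key\n"
            "p,ISI400,0,t0,test,0,100.0,C4\n"
            "p,ISI400,0,t0,test,1,99.5,C5\n"
            "p,ISI400,0,t0,test,2,300.0,C4\n")
        with pytest.raises(DataError, match="t0"):
            read_trials(path)
        loaded = read_trials(path, jitter_tolerance_ms=1.0)
        trial = loaded.test_trials("ISI400")[0]
        assert trial.onsets_ms == (99.5, 100.0, 300.0)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant,condition,onset_ms\np,ISI400,1.0\n")
        with pytest.raises(SchemaError):
            read_trials(path)


def _vlq(value):
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _smf(tracks, division=500, fmt=1):
    chunks = [b"MThd" + struct.pack(">IHHH", 6, fmt, len(tracks), division)]
    for events in tracks:
        body = b"".join(events) + _vlq(0) + b"\xff\x2f\x00"
        chunks.append(b"MTrk" + struct.pack(">I", len(body)) + body)
    return b"".join(chunks)


def _note_on(delta, channel, note=60, velocity=64):
    return _vlq(delta) + bytes([0x90 | channel, note, velocity])


def _tempo(delta, us_per_qn):
    return _vlq(delta) + b"\xff\x51\x03" + us_per_qn.to_bytes(3, "big")


class TestMidiImport:
    def test_onsets_follow_tempo_map(self, tmp_path):
        # 500 ticks/quarter at 500000 us/qn = 1 ms per tick, then the
        # tempo doubles at tick 1000 so each tick becomes 0.5 ms
        events = [
            _note_on(0, 0),
            _note_on(500, 0),
            _note_on(200, 1),        # other channel, ignored
            _tempo(300, 250_000),    # at tick 1000
            _note_on(500, 0),        # tick 1500 -> 1000 + 250 ms
        ]
        path = tmp_path / "taps.mid"
        path.write_bytes(_smf([events]))
        trials = read_midi_onsets(path, channel=0)
        assert len(trials) == 1
        assert trials[0].onsets_ms == pytest.approx((0.0, 500.0, 1250.0))
        other = read_midi_onsets(path, channel=1)
        assert len(other) == 1 and other[0].n_taps == 1

    def test_empty_track_yields_no_trials(self, tmp_path):
        path = tmp_path / "empty.mid"
        path.write_bytes(_smf([[]]))
        assert read_midi_onsets(path, channel=0) == []

    def test_gap_split_threshold(self, tmp_path):
        events = [_note_on(0, 0), _note_on(400, 0),
                  _note_on(5000, 0), _note_on(400, 0)]
        path = tmp_path / "two.mid"
        path.write_bytes(_smf([events]))
        trials = read_midi_onsets(path, channel=0, gap_split_ms=2000.0)
        assert [t.n_taps for t in trials] == [2, 2]
        assert trials[1].onsets_ms == pytest.approx((0.0, 400.0))

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "junk.mid"
        path.write_bytes(b"RIFFnotmidi")
        with pytest.raises(MidiFormatError):
            read_midi_onsets(path)
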