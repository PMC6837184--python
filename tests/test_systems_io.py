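"""Readers: FASTA, token streams, note-event tables."""

import gzip

import pandas as pd
import pytest

from cohsi.systems_io import (
    DURATION_CLASSES,
    components_from_notes,
    pitch_from_name,
    read_component_table,
    read_fasta,
    read_note_events,
    read_token_stream,
    write_component_table,
    write_note_events,
)


@pytest.fixture
def fasta_path(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">r1 basic\nAAB\n"
        ">r2 all-distinct\nACDEF\n"
        ">r3 case-folded multi-line\naab\nAB\n"
        ">r4 empty\n"
        ">r5 ambiguity codes\nAXXBZ\n"
    )
    return path


def test_read_fasta_lengths_and_alphabets(fasta_path):
    table = read_fasta(fasta_path)
    rows = {r.component_id: (r.length, r.alphabet) for r in table.itertuples()}
    assert rows["r1"] == (3, 2)
    assert rows["r2"] == (5, 5)
    assert rows["r3"] == (5, 2)  # case folding + line joining
    assert "r4" not in rows  # empty record skipped
    assert rows["r5"] == (5, 4)  # X, Z counted verbatim
    assert (table["source"] == "fasta").all()


def test_read_fasta_strict_residue_filter(fasta_path):
    # B is an ambiguity code, so r1 and r3 fall to the strict filter too
    table = read_fasta(fasta_path, strict_residues=True)
    assert set(table["component_id"]) == {"r2"}


def test_read_fasta_gzip(tmp_path, fasta_path):
    gz = tmp_path / "toy.fasta.gz"
    gz.write_bytes(gzip.compress(fasta_path.read_bytes()))
    assert read_fasta(gz).equals(read_fasta(fasta_path))


def test_read_fasta_rejects_malformed_header(tmp_path):
    bad = tmp_path / "bad.fasta"
    bad.write_text("AAB\n>r1\nCCC\n")
    with pytest.raises(ValueError, match="malformed"):
        read_fasta(bad)


def test_read_token_stream(tmp_path):
    path = tmp_path / "stream.txt"
    path.write_text("if ( x ) ;\na a a b\n\n# comment line\nz\n")
    table = read_token_stream(path)
    assert list(zip(table["length"], table["alphabet"])) == [(5, 5), (4, 2), (1, 1)]
    assert len(table) == 3


def test_read_token_stream_empty_file_errors(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("# only a comment\n\n")
    with pytest.raises(ValueError):
        read_token_stream(path)


@pytest.fixture
def note_events():
    return pd.DataFrame(
        {
            "composition_id": ["c1", "c1", "c1", "c2", "c2"],
            "pitch": [40, 40, 44, 10, 10],
            "duration_class": ["minim", "quaver", "minim", "crotchet", "crotchet"],
        }
    )


def test_components_from_notes_alphabets(note_events):
    no_dur = components_from_notes(note_events, with_duration=False)
    with_dur = components_from_notes(note_events, with_duration=True)
    c1_nd = no_dur[no_dur["component_id"] == "c1"].iloc[0]
    c1_wd = with_dur[with_dur["component_id"] == "c1"].iloc[0]
    assert (c1_nd["length"], c1_nd["alphabet"]) == (3, 2)  # a' = 2 pitches
    assert (c1_wd["length"], c1_wd["alphabet"]) == (3, 3)  # a'' = 3 pairs
    c2_wd = with_dur[with_dur["component_id"] == "c2"].iloc[0]
    assert (c2_wd["length"], c2_wd["alphabet"]) == (2, 1)  # same pitch+duration


def test_note_length_invariant_to_categorisation(note_events):
    no_dur = components_from_notes(note_events, with_duration=False)
    with_dur = components_from_notes(note_events, with_duration=True)
    assert no_dur["length"].tolist() == with_dur["length"].tolist()
    ratio = with_dur["alphabet"] / no_dur["alphabet"]
    assert ((ratio >= 1) & (ratio <= len(DURATION_CLASSES))).all()


def test_note_event_validation(tmp_path, note_events):
    bad = note_events.copy()
    bad.loc[2, "duration_class"] = "dotted-minim"
    path = tmp_path / "notes.tsv"
    write_note_events(bad, path)
    with pytest.raises(ValueError, match="dotted-minim"):
        read_note_events(path)
    with pytest.raises(ValueError, match="dotted-minim"):
        components_from_notes(bad)
    bad2 = note_events.copy()
    bad2.loc[0, "pitch"] = 90
    write_note_events(bad2, path)
    with pytest.raises(ValueError, match="pitch"):
        read_note_events(path)


def test_note_events_tsv_roundtrip(tmp_path, note_events):
    path = tmp_path / "notes.tsv"
    write_note_events(note_events, path)
    assert read_note_events(path).equals(note_events)


def test_component_table_tsv_roundtrip(tmp_path, note_events):
    table = components_from_notes(note_events)
    path = tmp_path / "components.tsv"
    write_component_table(table, path)
    assert read_component_table(path).equals(table)


@pytest.mark.parametrize(
    "name, key",
    [("A0", 1), ("C4", 40), ("A4", 49), ("F#3", 34), ("Bb3", 38), ("C8", 88)],
)
def test_pitch_from_name(name, key):
    assert pitch_from_name(name) == key


@pytest.mark.parametrize("name", ["H2", "C9", "A-1", "xyz"])
def test_pitch_from_name_rejects(name):
    with pytest.raises(ValueError):
        pitch_from_name(name)
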