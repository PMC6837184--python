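"""Readers turning real-world inputs into component tables.

Every supported source — proteome-style FASTA files, whitespace-tokenised
text streams, and note-event tables standing in for digital-music extracts —
reduces to the same two measurements per component: total length ``t`` in
tokens and unique alphabet ``a`` (distinct tokens actually used).  Those two
numbers are all the downstream theory consumes; token meaning is deliberately
discarded.

Declared alphabet ceilings per source: 26 residue letters for FASTA, 88
piano-key pitches for notes without duration, 88 x 7 = 616 (pitch, duration)
pairs with duration.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "DURATION_CLASSES",
    "GENETIC_RESIDUES",
    "read_fasta",
    "read_token_stream",
    "read_note_events",
    "write_note_events",
    "components_from_notes",
    "write_component_table",
    "read_component_table",
    "pitch_from_name",
]

logger = logging.getLogger(__name__)

#: The seven standard note durations, as fractions of a whole note from
#: breve (2) down to demisemiquaver (1/32).  Rarer values off either end of
#: this list are rejected.
DURATION_CLASSES = (
    "breve",
    "semibreve",
    "minim",
    "crotchet",
    "quaver",
    "semiquaver",
    "demisemiquaver",
)

#: One-letter codes of the 20 genetically encoded amino acids plus
#: selenocysteine (U) and pyrrolysine (O) — the 22-letter residue alphabet.
GENETIC_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYUO")

MAX_PITCH = 88
_ALPHABET_CEILING = {
    "fasta": 26,
    "tokens": None,
    "notes_pitch": MAX_PITCH,
    "notes_pitch_duration": MAX_PITCH * len(DURATION_CLASSES),
}

_COMPONENT_COLUMNS = ["component_id", "length", "alphabet", "source"]


def _make_table(rows: list[tuple[str, int, int]], source: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["component_id", "length", "alphabet"])
    df["source"] = source
    ceiling = _ALPHABET_CEILING[source]
    bad = df[(df["alphabet"] < 1) | (df["alphabet"] > df["length"])]
    if len(bad):
        raise ValueError(
            f"invalid rows (need 1 <= alphabet <= length): {bad.to_dict('records')}"
        )
    if ceiling is not None and (df["alphabet"] > ceiling).any():
        raise ValueError(f"alphabet exceeds the {source} ceiling of {ceiling}")
    return df


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def read_fasta(path, strict_residues: bool = False) -> pd.DataFrame:
    """Component table from a (optionally gzipped) FASTA file.

    Length = residue count after joining sequence lines and stripping
    whitespace; alphabet = distinct residue characters after uppercasing.
    Characters are taken verbatim — ambiguity codes (B, Z, X) and the rare
    U/O residues count as distinct tokens — unless ``strict_residues`` drops
    records containing characters outside the 22-letter genetic alphabet.
    Empty records are skipped with a logged warning.
    """
    rows: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            raise ValueError(f"{path}: empty file")
        if first != ">":
            raise ValueError(f"{path}: malformed FASTA (must start with '>')")
        fh.seek(0)
        for record in SeqIO.parse(fh, "fasta"):
            seq = re.sub(r"\s+", "", str(record.seq)).upper()
            if not seq:
                logger.warning("skipping empty FASTA record %r", record.id)
                continue
            if strict_residues and not set(seq) <= GENETIC_RESIDUES:
                logger.warning(
                    "dropping record %r with non-genetic residues", record.id
                )
                continue
            rows.append((record.id, len(seq), len(set(seq))))
    return _make_table(rows, "fasta")


def read_token_stream(path) -> pd.DataFrame:
    """Component table from plain text: one component per line, tokens
    whitespace-separated; blank lines and '#' comment lines ignored."""
    rows: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            rows.append((f"line{lineno}", len(tokens), len(set(tokens))))
    if not rows:
        raise ValueError(f"{path}: no token lines found")
    return _make_table(rows, "tokens")


def read_note_events(path) -> pd.DataFrame:
    """Note-event table from TSV with header
    ``composition_id<TAB>pitch<TAB>duration_class``.

    Pitch is an integer piano-key index 1..88; duration_class must be one of
    the seven standard classes.  Validation errors name the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"composition_id": str})
    expected = ["composition_id", "pitch", "duration_class"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    bad_pitch = df[(df["pitch"] < 1) | (df["pitch"] > MAX_PITCH)]
    if len(bad_pitch):
        raise ValueError(f"pitch outside 1..{MAX_PITCH} at rows {list(bad_pitch.index)}")
    bad_dur = df[~df["duration_class"].isin(DURATION_CLASSES)]
    if len(bad_dur):
        first = bad_dur.iloc[0]
        raise ValueError(
            f"unknown duration_class {first['duration_class']!r} at row "
            f"{bad_dur.index[0]} (composition {first['composition_id']!r})"
        )
    return df


def write_note_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def components_from_notes(events: pd.DataFrame, with_duration: bool = False) -> pd.DataFrame:
    """Component table from note events, grouped by composition.

    Length is the event count and is identical under both alphabets (the
    total number of tokens cannot depend on how they are categorised);
    alphabet is the number of distinct pitches (``with_duration=False``,
    <= 88) or distinct (pitch, duration_class) pairs (True, <= 616).
    """
    if "duration_class" in events.columns:
        bad = events[~events["duration_class"].isin(DURATION_CLASSES)]
        if len(bad):
            raise ValueError(
                f"unknown duration_class {bad.iloc[0]['duration_class']!r} at row "
                f"{bad.index[0]}"
            )
    rows = []
    for comp_id, grp in events.groupby("composition_id", sort=True):
        t = len(grp)
        if with_duration:
            a = len(set(zip(grp["pitch"], grp["duration_class"])))
        else:
            a = grp["pitch"].nunique()
        rows.append((str(comp_id), t, a))
    source = "notes_pitch_duration" if with_duration else "notes_pitch"
    return _make_table(rows, source)


def write_component_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_component_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"component_id": str, "source": str})
    if list(df.columns) != _COMPONENT_COLUMNS:
        raise ValueError(f"{path}: expected columns {_COMPONENT_COLUMNS}")
    return df


_NOTE_OFFSETS = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


def pitch_from_name(name: str) -> int:
    """Piano-key index 1..88 from scientific pitch notation (A0=1, C8=88).

    Accepts an optional '#' (sharp) or 'b' (flat) between letter and octave,
    e.g. 'C4' -> 40, 'A4' -> 49, 'F#3' -> 34.
    """
    m = re.fullmatch(r"([A-Ga-g])([#b]?)(-?\d+)", name.strip())
    if not m:
        raise ValueError(f"cannot parse pitch name {name!r}")
    letter, accidental, octave = m.group(1).upper(), m.group(2), int(m.group(3))
    semitone = _NOTE_OFFSETS[letter] + (1 if accidental == "#" else -1 if accidental == "b" else 0)
    midi = 12 * (octave + 1) + semitone
    key = midi - 20  # A0 = MIDI 21 = key 1
    if not 1 <= key <= MAX_PITCH:
        raise ValueError(f"{name!r} is outside the 88-key range")
    return key
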