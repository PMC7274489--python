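"""Reading, validating and writing protein sequence data and predictions.

Sequences travel as :class:`ProteinRecord` objects.  Training labels come
either from a two-column sidecar TSV (``id<TAB>label``) or, as a
fallback, from a ``|label=`` suffix on the FASTA id token.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from plantloc.tables import STANDARD_AA

_STANDARD_SET = frozenset(STANDARD_AA)

#: Residues routed per the ambiguity policy (not part of the 20-letter
#: standard alphabet): B, J, O, U, X, Z and anything else non-standard.
DEFAULT_MIN_LENGTH = 50


class FastaFormatError(ValueError):
    """Malformed or empty FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence with an optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClassVocabulary:
    """The localization class scheme: 11 single compartments plus 3
    dual (compound) classes, each mapping to a pair of singles."""

    single_classes: tuple[str, ...]
    dual_classes: tuple[str, ...]
    dual_pairs: Mapping[str, tuple[str, str]]

    @property
    def all_classes(self) -> tuple[str, ...]:
        return self.single_classes + self.dual_classes

    def __post_init__(self):
        if len(self.single_classes) != 11:
            raise ValueError("expected 11 single classes")
        if len(self.dual_classes) != 3:
            raise ValueError("expected 3 dual classes")
        if len(set(self.all_classes)) != 14:
            raise ValueError("class names must be distinct")
        for dual, pair in self.dual_pairs.items():
            if dual not in self.dual_classes:
                raise ValueError(f"unknown dual class {dual!r}")
            for single in pair:
                if single not in self.single_classes:
                    raise ValueError(f"unknown single class {single!r}")


DEFAULT_VOCABULARY = ClassVocabulary(
    single_classes=(
        "plastid",
        "cytoplasm",
        "extracellular",
        "nucleus",
        "mitochondrion",
        "cell membrane",
        "Golgi apparatus",
        "endoplasmic reticulum",
        "vacuole",
        "peroxisome",
        "cell wall",
    ),
    dual_classes=("mito-plastid", "cyto-nucleus", "cyto-Golgi"),
    dual_pairs={
        "mito-plastid": ("mitochondrion", "plastid"),
        "cyto-nucleus": ("cytoplasm", "nucleus"),
        "cyto-Golgi": ("cytoplasm", "Golgi apparatus"),
    },
)


def _split_id_token(token: str) -> tuple[str, str | None]:
    if "|label=" in token:
        rid, label = token.split("|label=", 1)
        return rid, label or None
    return token, None


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-FASTA file into records, preserving file order.

    The header token before the first whitespace becomes the id (a
    ``|label=<class>`` suffix on it is split off into the label);
    sequence lines are concatenated and uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, label = _split_id_token(entry.id)
        seq = str(entry.seq).upper().replace(" ", "")
        if not rid:
            raise FastaFormatError(f"record with empty id in {path}")
        if not seq:
            raise FastaFormatError(f"record {rid!r} has an empty sequence")
        records.append(ProteinRecord(id=rid, sequence=seq, label=label))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(path, records: Iterable[ProteinRecord], line_width: int = 60) -> None:
    """Write records as multi-FASTA; labels are embedded as a
    ``|label=`` id suffix so labeled sets round-trip through one file."""
    entries = []
    for rec in records:
        rid = rec.id if rec.label is None else f"{rec.id}|label={rec.label}"
        entries.append(SeqRecord(Seq(rec.sequence), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(entries)


def read_labels(path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` TSV (header optional)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i + 1}: expected 2 columns")
            if i == 0 and parts[0].lower() in {"id", "identifier"}:
                continue
            labels[parts[0]] = parts[1]
    return labels


def write_labels(path, records: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} has no label")
            fh.write(f"{rec.id}\t{rec.label}\n")


def attach_labels(
    records: Sequence[ProteinRecord], labels: Mapping[str, str]
) -> list[ProteinRecord]:
    """Return records with labels joined in from a mapping; every
    record id must be present in the mapping."""
    missing = [rec.id for rec in records if rec.id not in labels]
    if missing:
        raise KeyError(f"no label for record id(s): {', '.join(missing[:5])}")
    return [replace(rec, label=labels[rec.id]) for rec in records]


def validate_records(
    records: Sequence[ProteinRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    on_ambiguous: str = "reject",
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Partition records into accepted and rejected.

    A record is accepted when its sequence is strictly longer than
    ``min_length`` and contains only the 20 standard residue letters.
    Ambiguous residues (B, J, O, U, X, Z, ...) are handled per policy:
    ``reject`` lists the record under rejected; ``drop`` removes the
    offending characters and re-checks the length.

    Returns ``(accepted, rejected)`` where rejected holds
    ``(id, reason)`` pairs; the two lists partition the input.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if on_ambiguous not in {"reject", "drop"}:
        raise ValueError("on_ambiguous must be 'reject' or 'drop'")

    accepted: list[ProteinRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        seq = rec.sequence
        bad = sorted(set(seq) - _STANDARD_SET)
        if bad:
            if on_ambiguous == "reject":
                rejected.append(
                    (rec.id, f"ambiguous residue {', '.join(bad)}")
                )
                continue
            seq = "".join(c for c in seq if c in _STANDARD_SET)
        if len(seq) <= min_length:
            rejected.append((rec.id, f"length <= {min_length}"))
            continue
        accepted.append(rec if seq == rec.sequence else replace(rec, sequence=seq))
    return accepted, rejected


def write_predictions(
    path,
    rows: Sequence[tuple[str, str, Mapping[str, float]]],
    class_list: Sequence[str],
    provenance: Sequence[str] = (),
) -> None:
    """Write predictions as TSV: id, predicted_class, then one score
    column per class in vocabulary order (6 decimal places).

    ``provenance`` lines, if given, are emitted first as ``#`` comments.
    """
    for rid, _cls, scores in rows:
        missing = set(class_list) - set(scores)
        if missing:
            raise ValueError(f"row {rid!r} missing scores for {sorted(missing)}")
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write("id\tpredicted_class\t" + "\t".join(class_list) + "\n")
        for rid, cls, scores in rows:
            vals = "\t".join(f"{scores[c]:.6f}" for c in class_list)
            fh.write(f"{rid}\t{cls}\t{vals}\n")


def read_predictions(path) -> tuple[list[str], list[tuple[str, str, dict[str, float]]]]:
    """Parse a predictions TSV back into ``(class_list, rows)``;
    ``#`` comment lines are skipped."""
    rows = []
    class_list: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if class_list is None:
                if parts[:2] != ["id", "predicted_class"]:
                    raise ValueError(f"{path}: unexpected header")
                class_list = parts[2:]
                continue
            scores = dict(zip(class_list, map(float, parts[2:])))
            rows.append((parts[0], parts[1], scores))
    if class_list is None:
        raise ValueError(f"{path}: empty predictions file")
    return class_list, rows
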