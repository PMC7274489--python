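"""Residue grouping tables, physicochemical property scales and the
amino-acid distance matrix used by the feature encoders.

All tables ship as versioned plain-text TSV files under
``plantloc/data`` and are loaded once per process.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letter -> index into alphabetically ordered arrays.
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("plantloc.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


@dataclass(frozen=True)
class GroupTable:
    """Bundle of all lookup tables the encoders depend on.

    Attributes
    ----------
    attribute_groups
        Ordered mapping attribute name -> triple of residue sets; the
        three groups partition the 20-letter alphabet and drive the
        composition/transition (CTD) recoding into classes 1/2/3.
    physchem_groups
        Ordered ``(name, residue set)`` pairs for the 21
        group-composition components of the physicochemical encoder;
        groups may overlap.
    atom_counts
        ``(20, 5)`` array of C/H/N/O/S atom counts per peptide-chain
        residue, rows in alphabetical residue order.
    qso_distance
        Symmetric ``(20, 20)`` nonnegative amino-acid physicochemical
        distance matrix with zero diagonal (normalized Grantham
        distances), indexed alphabetically.
    pseaac_properties
        ``(3, 20)`` array of hydrophobicity, hydrophilicity and
        side-chain mass, each standardized to mean 0 and unit
        population variance over the 20 residues.
    """

    attribute_groups: dict[str, tuple[frozenset, frozenset, frozenset]]
    physchem_groups: tuple[tuple[str, frozenset], ...]
    atom_counts: np.ndarray
    qso_distance: np.ndarray
    pseaac_properties: np.ndarray

    def ctd_codes(self, attribute: str) -> np.ndarray:
        """Class code (0, 1 or 2) of each residue under one attribute,
        as a length-20 array in alphabetical residue order."""
        groups = self.attribute_groups[attribute]
        codes = np.empty(20, dtype=np.int64)
        for cls, members in enumerate(groups):
            for aa in members:
                codes[AA_INDEX[aa]] = cls
        return codes


@functools.lru_cache(maxsize=1)
def default_group_table() -> GroupTable:
    """Load the shipped tables (cached)."""
    attr_rows = _read_tsv("ctd_groups.tsv")[1:]
    attribute_groups = {
        row[0]: tuple(frozenset(g) for g in row[1:4]) for row in attr_rows
    }
    for name, groups in attribute_groups.items():
        union = frozenset().union(*groups)
        if union != frozenset(STANDARD_AA) or sum(map(len, groups)) != 20:
            raise ValueError(f"groups for {name!r} do not partition the alphabet")

    pc_rows = _read_tsv("physchem_groups.tsv")[1:]
    physchem_groups = tuple((row[0], frozenset(row[1])) for row in pc_rows)

    atom_rows = _read_tsv("atom_counts.tsv")[1:]
    atom_counts = np.zeros((20, 5), dtype=np.float64)
    for row in atom_rows:
        atom_counts[AA_INDEX[row[0]]] = [float(x) for x in row[1:6]]

    dist_rows = _read_tsv("aa_distance.tsv")
    header = dist_rows[0][1:]
    if "".join(header) != STANDARD_AA:
        raise ValueError("distance matrix column order mismatch")
    qso_distance = np.array(
        [[float(x) for x in row[1:]] for row in dist_rows[1:]], dtype=np.float64
    )

    prop_rows = _read_tsv("pseaac_properties.tsv")[1:]
    raw = np.zeros((3, 20), dtype=np.float64)
    for row in prop_rows:
        raw[:, AA_INDEX[row[0]]] = [float(x) for x in row[1:4]]
    # classic PseAAC convention: zero mean, unit *population* variance
    props = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)

    return GroupTable(
        attribute_groups=attribute_groups,
        physchem_groups=physchem_groups,
        atom_counts=atom_counts,
        qso_distance=qso_distance,
        pseaac_properties=props,
    )
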