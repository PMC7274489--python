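"""Sequence-derived feature encoders.

Eight descriptor families are provided, each a pure function of the
sequence (and its parameters):

====================  ====  =============================================
name                  dim   description
====================  ====  =============================================
AAC                   20    amino-acid composition (residue fractions)
DIPEP                 400   overlapping dipeptide composition
PseAAC                20+λ  type-1 pseudo amino-acid composition
NCC                   60    AAC of N-terminal / center / C-terminal parts
PHYSCHEM              26    21 physicochemical group fractions + 5 atomic
CTDC                  21    class composition per 7 grouping attributes
CTDT                  21    adjacent class-transition frequencies
QSO                   20+maxlag  quasi-sequence-order descriptors
====================  ====  =============================================

Hybrid encoders are hyphenated concatenations, e.g. ``PseAAC-NCC-DIPEP``
(the best-performing hybrid for localization prediction); their output
is the parts' vectors joined left to right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from plantloc.tables import AA_INDEX, STANDARD_AA, GroupTable, default_group_table

__all__ = [
    "EncodingError", "EncoderRecipe", "FeatureVector", "FeatureMatrix",
    "make_recipe", "encode", "encode_many",
    "encode_aac", "encode_dipep", "encode_pseaac", "encode_ncc",
    "encode_physchem", "encode_ctdc", "encode_ctdt", "encode_qso",
    "encode_hybrid", "BASE_ENCODERS",
]

BASE_ENCODERS = ("AAC", "DIPEP", "PseAAC", "NCC", "PHYSCHEM", "CTDC", "CTDT", "QSO")

DEFAULT_PARAMS = {
    "lam": 20,            # PseAAC sequence-order lag count (λ)
    "w_pse": 0.05,        # PseAAC weighting factor
    "maxlag": 30,         # QSO maximum lag
    "w_qso": 0.1,         # QSO weighting factor
    "terminal_length": 25,  # NCC terminal segment length
}

_CTD_PAIRS = ((0, 1), (0, 2), (1, 2))


class EncodingError(ValueError):
    """A sequence violates an encoder precondition."""


@dataclass(frozen=True)
class EncoderRecipe:
    """Name, parameters and frozen output component names of an encoder."""

    name: str
    parameters: Mapping[str, float]
    feature_names: tuple[str, ...]

    @property
    def dimension(self) -> int:
        return len(self.feature_names)

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self.name.split("-")) if "-" in self.name else (self.name,)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    recipe: EncoderRecipe
    record_id: str = ""

    def __post_init__(self):
        if len(self.values) != self.recipe.dimension:
            raise ValueError("value count does not match recipe dimension")


@dataclass(frozen=True)
class FeatureMatrix:
    """Row-per-sequence stack of feature vectors under one recipe."""

    values: np.ndarray
    recipe: EncoderRecipe
    record_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _seq_to_idx(sequence: str) -> np.ndarray:
    if not sequence:
        raise EncodingError("empty sequence")
    try:
        return np.array([AA_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise EncodingError(f"non-standard residue {exc.args[0]!r}") from None


def _table(table: GroupTable | None) -> GroupTable:
    return table if table is not None else default_group_table()


# ---------------------------------------------------------------------------
# base encoders (raw ndarray core + FeatureVector wrappers)

def _aac(idx: np.ndarray) -> np.ndarray:
    return np.bincount(idx, minlength=20) / len(idx)


def _dipep(idx: np.ndarray) -> np.ndarray:
    if len(idx) < 2:
        raise EncodingError("dipeptide composition needs length >= 2")
    codes = idx[:-1] * 20 + idx[1:]
    return np.bincount(codes, minlength=400) / (len(idx) - 1)


def _pseaac(idx: np.ndarray, lam: int, w_pse: float, table: GroupTable) -> np.ndarray:
    n = len(idx)
    if lam < 0:
        raise EncodingError("lambda must be nonnegative")
    if lam >= n:
        raise EncodingError(f"lambda ({lam}) must be < sequence length ({n})")
    props = table.pseaac_properties  # (3, 20), standardized
    freqs = _aac(idx)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        d = props[:, idx[:-j]] - props[:, idx[j:]]
        thetas[j - 1] = np.mean(d * d)  # mean over properties and positions
    denom = freqs.sum() + w_pse * thetas.sum()
    return np.concatenate([freqs / denom, w_pse * thetas / denom])


def _ncc(idx: np.ndarray, terminal_length: int) -> np.ndarray:
    t = terminal_length
    if len(idx) <= 2 * t:
        raise EncodingError(
            f"sequence length ({len(idx)}) must exceed twice the terminal "
            f"length (2*{t}) for N-Center-C composition"
        )
    return np.concatenate([_aac(idx[:t]), _aac(idx[t:-t]), _aac(idx[-t:])])


def _physchem(idx: np.ndarray, table: GroupTable) -> np.ndarray:
    n = len(idx)
    out = np.empty(26)
    for k, (_name, members) in enumerate(table.physchem_groups):
        member_idx = [AA_INDEX[a] for a in members]
        out[k] = np.isin(idx, member_idx).sum() / n
    atoms = table.atom_counts[idx].sum(axis=0)  # totals for C,H,N,O,S
    out[21:] = atoms / atoms.sum()
    return out


def _ctdc(idx: np.ndarray, table: GroupTable) -> np.ndarray:
    out = np.empty(21)
    for k, attr in enumerate(table.attribute_groups):
        coded = table.ctd_codes(attr)[idx]
        out[3 * k : 3 * k + 3] = np.bincount(coded, minlength=3) / len(idx)
    return out


def _ctdt(idx: np.ndarray, table: GroupTable) -> np.ndarray:
    n = len(idx)
    if n < 2:
        raise EncodingError("transition descriptors need length >= 2")
    out = np.empty(21)
    for k, attr in enumerate(table.attribute_groups):
        coded = table.ctd_codes(attr)[idx]
        a, b = coded[:-1], coded[1:]
        for p, (r, s) in enumerate(_CTD_PAIRS):
            n_rs = np.count_nonzero((a == r) & (b == s))
            n_sr = np.count_nonzero((a == s) & (b == r))
            out[3 * k + p] = (n_rs + n_sr) / (n - 1)
    return out


def _qso(idx: np.ndarray, maxlag: int, w_qso: float, table: GroupTable) -> np.ndarray:
    n = len(idx)
    if maxlag < 1:
        raise EncodingError("maxlag must be >= 1")
    if maxlag >= n:
        raise EncodingError(f"maxlag ({maxlag}) must be < sequence length ({n})")
    dist = table.qso_distance
    counts = np.bincount(idx, minlength=20).astype(np.float64)
    taus = np.empty(maxlag)
    for d in range(1, maxlag + 1):
        dd = dist[idx[:-d], idx[d:]]
        taus[d - 1] = np.sum(dd * dd)
    denom = counts.sum() + w_qso * taus.sum()
    return np.concatenate([counts / denom, w_qso * taus / denom])


def encode_aac(sequence: str, table: GroupTable | None = None, record_id: str = "") -> FeatureVector:
    """20-d amino-acid composition: fraction of each residue,
    alphabetical order."""
    return FeatureVector(_aac(_seq_to_idx(sequence)), make_recipe("AAC"), record_id)


def encode_dipep(sequence: str, table: GroupTable | None = None, record_id: str = "") -> FeatureVector:
    """400-d overlapping dipeptide composition: count of each ordered
    residue pair over N-1 windows, row-major alphabetical order."""
    return FeatureVector(_dipep(_seq_to_idx(sequence)), make_recipe("DIPEP"), record_id)


def encode_pseaac(
    sequence: str,
    lam: int = DEFAULT_PARAMS["lam"],
    w_pse: float = DEFAULT_PARAMS["w_pse"],
    table: GroupTable | None = None,
    record_id: str = "",
) -> FeatureVector:
    """(20+λ)-d classic type-1 pseudo amino-acid composition.

    The first 20 components are residue frequencies and the last λ are
    weighted sequence-order correlation factors θ_j, all sharing the
    denominator Σf + w·Σθ.  θ_j averages, over positions i, the mean
    squared difference of three standardized physicochemical properties
    (hydrophobicity, hydrophilicity, side-chain mass) between residues
    j positions apart.
    """
    tab = _table(table)
    vec = _pseaac(_seq_to_idx(sequence), lam, w_pse, tab)
    return FeatureVector(vec, make_recipe("PseAAC", lam=lam, w_pse=w_pse), record_id)


def encode_ncc(
    sequence: str,
    terminal_length: int = DEFAULT_PARAMS["terminal_length"],
    table: GroupTable | None = None,
    record_id: str = "",
) -> FeatureVector:
    """60-d N-Center-C terminal composition: AAC of the first
    ``terminal_length`` residues, the middle remainder, and the last
    ``terminal_length`` residues, concatenated in that order."""
    vec = _ncc(_seq_to_idx(sequence), terminal_length)
    return FeatureVector(
        vec, make_recipe("NCC", terminal_length=terminal_length), record_id
    )


def encode_physchem(sequence: str, table: GroupTable | None = None, record_id: str = "") -> FeatureVector:
    """26-d physicochemical composition: fractions of residues in 21
    (possibly overlapping) property groups plus the fractions of C, H,
    N, O and S atoms over all residue atoms."""
    vec = _physchem(_seq_to_idx(sequence), _table(table))
    return FeatureVector(vec, make_recipe("PHYSCHEM"), record_id)


def encode_ctdc(sequence: str, table: GroupTable | None = None, record_id: str = "") -> FeatureVector:
    """21-d CTD composition: for each of 7 grouping attributes the
    sequence is recoded into classes 1/2/3 and the class fractions
    n_r/N are emitted (attribute-major order)."""
    vec = _ctdc(_seq_to_idx(sequence), _table(table))
    return FeatureVector(vec, make_recipe("CTDC"), record_id)


def encode_ctdt(sequence: str, table: GroupTable | None = None, record_id: str = "") -> FeatureVector:
    """21-d CTD transition: per attribute, the frequency
    (n_rs + n_sr)/(N-1) of adjacent positions switching between each
    unordered class pair (1,2), (1,3), (2,3)."""
    vec = _ctdt(_seq_to_idx(sequence), _table(table))
    return FeatureVector(vec, make_recipe("CTDT"), record_id)


def encode_qso(
    sequence: str,
    maxlag: int = DEFAULT_PARAMS["maxlag"],
    w_qso: float = DEFAULT_PARAMS["w_qso"],
    table: GroupTable | None = None,
    record_id: str = "",
) -> FeatureVector:
    """(20+maxlag)-d quasi-sequence-order descriptors.

    τ_d sums the squared physicochemical distance between residues d
    positions apart; the first 20 components are residue counts and the
    last maxlag are w·τ_d, all normalized by N + w·Στ so the whole
    vector sums to 1.
    """
    tab = _table(table)
    vec = _qso(_seq_to_idx(sequence), maxlag, w_qso, tab)
    return FeatureVector(
        vec, make_recipe("QSO", maxlag=maxlag, w_qso=w_qso), record_id
    )


# ---------------------------------------------------------------------------
# recipe construction and dispatch

def _base_feature_names(name: str, params: Mapping[str, float], table: GroupTable) -> tuple[str, ...]:
    if name == "AAC":
        return tuple(STANDARD_AA)
    if name == "DIPEP":
        return tuple(a + b for a in STANDARD_AA for b in STANDARD_AA)
    if name == "PseAAC":
        lam = int(params["lam"])
        return tuple(STANDARD_AA) + tuple(f"theta{j}" for j in range(1, lam + 1))
    if name == "NCC":
        return tuple(
            f"{block}.{a}" for block in ("N", "Center", "C") for a in STANDARD_AA
        )
    if name == "PHYSCHEM":
        groups = tuple(g for g, _ in table.physchem_groups)
        return groups + tuple(f"atom_{e}" for e in "CHNOS")
    if name == "CTDC":
        return tuple(
            f"{attr}.C{r}" for attr in table.attribute_groups for r in (1, 2, 3)
        )
    if name == "CTDT":
        return tuple(
            f"{attr}.T{r + 1}{s + 1}"
            for attr in table.attribute_groups
            for r, s in _CTD_PAIRS
        )
    if name == "QSO":
        maxlag = int(params["maxlag"])
        return tuple(STANDARD_AA) + tuple(f"tau{d}" for d in range(1, maxlag + 1))
    raise ValueError(f"unknown encoder {name!r}")


def make_recipe(name: str, table: GroupTable | None = None, **params) -> EncoderRecipe:
    """Build an :class:`EncoderRecipe` for a base or hyphenated hybrid
    encoder name; unspecified parameters take their defaults."""
    tab = _table(table)
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ValueError(f"unknown encoder parameter(s): {sorted(unknown)}")
    full = {**DEFAULT_PARAMS, **params}
    parts = name.split("-")
    for part in parts:
        if part not in BASE_ENCODERS:
            raise ValueError(f"unknown encoder {part!r} in {name!r}")
    if len(parts) == 1:
        names = _base_feature_names(name, full, tab)
    else:
        names = tuple(
            f"{part}:{comp}"
            for part in parts
            for comp in _base_feature_names(part, full, tab)
        )
    return EncoderRecipe(name=name, parameters=full, feature_names=names)


def _encode_base(idx: np.ndarray, name: str, p: Mapping[str, float], table: GroupTable) -> np.ndarray:
    if name == "AAC":
        return _aac(idx)
    if name == "DIPEP":
        return _dipep(idx)
    if name == "PseAAC":
        return _pseaac(idx, int(p["lam"]), float(p["w_pse"]), table)
    if name == "NCC":
        return _ncc(idx, int(p["terminal_length"]))
    if name == "PHYSCHEM":
        return _physchem(idx, table)
    if name == "CTDC":
        return _ctdc(idx, table)
    if name == "CTDT":
        return _ctdt(idx, table)
    if name == "QSO":
        return _qso(idx, int(p["maxlag"]), float(p["w_qso"]), table)
    raise ValueError(f"unknown encoder {name!r}")


def encode(
    sequence: str,
    recipe: EncoderRecipe,
    table: GroupTable | None = None,
    record_id: str = "",
) -> FeatureVector:
    """Encode one sequence under a recipe (base or hybrid)."""
    tab = _table(table)
    idx = _seq_to_idx(sequence)
    blocks = []
    for part in recipe.parts:
        try:
            blocks.append(_encode_base(idx, part, recipe.parameters, tab))
        except EncodingError as exc:
            raise EncodingError(f"{part}: {exc}") from None
    return FeatureVector(np.concatenate(blocks), recipe, record_id)


def encode_hybrid(
    sequence: str,
    parts: Sequence[str],
    table: GroupTable | None = None,
    record_id: str = "",
    **params,
) -> FeatureVector:
    """Concatenate several encoders' outputs in the given order."""
    recipe = make_recipe("-".join(parts), table=table, **params)
    return encode(sequence, recipe, table=table, record_id=record_id)


def encode_many(records, recipe: EncoderRecipe, table: GroupTable | None = None) -> FeatureMatrix:
    """Encode a list of :class:`~plantloc.seqio.ProteinRecord` (or any
    objects with ``id`` and ``sequence``) into a feature matrix."""
    tab = _table(table)
    rows = [encode(rec.sequence, recipe, table=tab, record_id=rec.id) for rec in records]
    values = (
        np.vstack([r.values for r in rows])
        if rows
        else np.empty((0, recipe.dimension))
    )
    return FeatureMatrix(values, recipe, tuple(r.record_id for r in rows))
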