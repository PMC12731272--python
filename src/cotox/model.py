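"""Consumer-resource-toxin (CRT) models.

A CRT model abstracts a microbial community as two sign tables: a food
resource table (taxa x resources; +1 produce, -1 require, 0 neither) and a
toxin table (taxa x toxins; +1 produce, -1 sensitive, 0 unaffected).
Quantitative stoichiometry, rates and abundances are deliberately out of
scope: the tables only encode *which* cross-feeding dependencies and
mutual-exclusion interactions exist.

The module provides the domain types, validation, per-taxon accessors,
TSV/JSON (de)serialization and a seeded random-model generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ModelFormatError, ParameterError, UnknownLabelError

_SIGN_TO_CHAR = {1: "+", -1: "-", 0: "0"}
_CHAR_TO_SIGN = {"+": 1, "-": -1, "0": 0}


def _coerce_table(table, n_cols: int) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int8)
    if arr.ndim == 1 and arr.size == 0:
        arr = arr.reshape((0, n_cols))
    return arr


@dataclass(frozen=True)
class TaxonProfile:
    """Signed-row view of one taxon: what it needs, makes and fears."""

    required_resources: frozenset[str]
    produced_resources: frozenset[str]
    produced_toxins: frozenset[str]
    sensitive_toxins: frozenset[str]


class CRTModel:
    """A consumer-resource-toxin model.

    Parameters
    ----------
    taxa, resources, toxins
        Ordered, duplicate-free label sequences.
    food_table
        ``S x M`` array over ``{-1, 0, +1}``: +1 the taxon produces the
        resource, -1 it requires it.
    toxin_table
        ``S x T`` array over ``{-1, 0, +1}``: +1 the taxon produces the
        toxin, -1 it is sensitive to it.
    """

    def __init__(self, taxa, resources, toxins, food_table, toxin_table):
        self.taxa: tuple[str, ...] = tuple(taxa)
        self.resources: tuple[str, ...] = tuple(resources)
        self.toxins: tuple[str, ...] = tuple(toxins)
        # Tables are stored as given (no silent reshaping) so that
        # validate_model can report genuine shape mismatches.
        self.food_table = _coerce_table(food_table, len(self.resources))
        self.toxin_table = _coerce_table(toxin_table, len(self.toxins))
        self.food_table.setflags(write=False)
        self.toxin_table.setflags(write=False)
        self._index = {t: i for i, t in enumerate(self.taxa)}

    # -- basic protocol ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_resources(self) -> int:
        return len(self.resources)

    @property
    def n_toxins(self) -> int:
        return len(self.toxins)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise UnknownLabelError(f"unknown taxon {taxon!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, CRTModel):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.resources == other.resources
            and self.toxins == other.toxins
            and np.array_equal(self.food_table, other.food_table)
            and np.array_equal(self.toxin_table, other.toxin_table)
        )

    def __repr__(self) -> str:
        return (
            f"CRTModel(S={self.n_taxa}, M={self.n_resources}, "
            f"T={self.n_toxins})"
        )


@dataclass(frozen=True)
class GenerationParams:
    """Parameters of the random-model generator.

    Food-table cells are drawn i.i.d.: ``+`` with ``p_food_produce``, ``-``
    with ``p_food_require``, ``0`` otherwise (defaults 1/3 each).  Toxin
    cells use ``p_toxin_produce`` / ``p_toxin_sensitive`` (defaults 0.1,
    the standard setting of the simulation studies in this package).
    """

    S: int
    M: int
    T: int
    p_food_produce: float = 1.0 / 3.0
    p_food_require: float = 1.0 / 3.0
    p_toxin_produce: float = 0.1
    p_toxin_sensitive: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if min(self.S, self.M, self.T) < 0:
            raise ParameterError("S, M, T must be non-negative")
        for name in ("p_food_produce", "p_food_require",
                     "p_toxin_produce", "p_toxin_sensitive"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if self.p_food_produce + self.p_food_require > 1.0 + 1e-12:
            raise ParameterError("p_food_produce + p_food_require > 1")
        if self.p_toxin_produce + self.p_toxin_sensitive > 1.0 + 1e-12:
            raise ParameterError("p_toxin_produce + p_toxin_sensitive > 1")


def validate_model(model: CRTModel) -> list[str]:
    """Report every invariant violation of ``model`` (empty list = valid).

    Checks label uniqueness, table shapes and the sign domain.  Production
    and requirement of the same resource by one taxon cannot be expressed
    at all: a single table cell encodes the one relation between a pair.
    """
    report: list[str] = []
    for kind, labels in (("taxa", model.taxa), ("resources", model.resources),
                         ("toxins", model.toxins)):
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                report.append(f"duplicate {kind} label {lab!r}")
            seen.add(lab)
    S = len(model.taxa)
    if model.food_table.shape != (S, len(model.resources)):
        report.append(
            f"food table shape {model.food_table.shape} does not match "
            f"(taxa={S}, resources={len(model.resources)})"
        )
    if model.toxin_table.shape != (S, len(model.toxins)):
        report.append(
            "taxa dimension mismatch: toxin table shape "
            f"{model.toxin_table.shape} does not match "
            f"(taxa={S}, toxins={len(model.toxins)})"
        )
    for name, table, cols in (
        ("food_table", model.food_table, model.resources),
        ("toxin_table", model.toxin_table, model.toxins),
    ):
        bad = np.argwhere(~np.isin(table, (-1, 0, 1)))
        for r, c in bad[:50]:
            report.append(
                f"{name} entry {table[r, c]} at (taxon {model.taxa[r]!r}, "
                f"column {cols[c]!r}) outside {{-1, 0, +1}}"
            )
    return report


def taxon_profile(model: CRTModel, taxon: str) -> TaxonProfile:
    """The four signed-row sets (required/produced resources, produced/
    sensitive toxins) of one taxon."""
    i = model.taxon_index(taxon)
    food = model.food_table[i]
    tox = model.toxin_table[i]
    return TaxonProfile(
        required_resources=frozenset(
            model.resources[j] for j in np.flatnonzero(food == -1)),
        produced_resources=frozenset(
            model.resources[j] for j in np.flatnonzero(food == 1)),
        produced_toxins=frozenset(
            model.toxins[j] for j in np.flatnonzero(tox == 1)),
        sensitive_toxins=frozenset(
            model.toxins[j] for j in np.flatnonzero(tox == -1)),
    )


# -- serialization ---------------------------------------------------------

def write_model(model: CRTModel, format: str = "tsv") -> str:
    """Serialize a model to TSV (the compact sign-table layout) or JSON."""
    if format == "json":
        return json.dumps(
            {
                "taxa": list(model.taxa),
                "resources": list(model.resources),
                "toxins": list(model.toxins),
                "food_table": model.food_table.tolist(),
                "toxin_table": model.toxin_table.tolist(),
            },
            indent=1,
        )
    if format != "tsv":
        raise ParameterError(f"unknown model format {format!r}")
    header = ["taxon", *model.resources, "|", *model.toxins]
    lines = ["\t".join(header)]
    for i, taxon in enumerate(model.taxa):
        cells = [_SIGN_TO_CHAR[int(v)] for v in model.food_table[i]]
        tox_cells = [_SIGN_TO_CHAR[int(v)] for v in model.toxin_table[i]]
        lines.append("\t".join([taxon, *cells, "|", *tox_cells]))
    return "\n".join(lines) + "\n"


def read_model(source: str, format: str = "tsv") -> CRTModel:
    """Parse a model from TSV or JSON text (inverse of :func:`write_model`)."""
    if format == "json":
        doc = json.loads(source)
        try:
            model = CRTModel(doc["taxa"], doc["resources"], doc["toxins"],
                             doc["food_table"], doc["toxin_table"])
        except (KeyError, ValueError) as exc:
            raise ModelFormatError(f"bad model JSON: {exc}") from exc
        _raise_on_violations(model)
        return model
    if format != "tsv":
        raise ParameterError(f"unknown model format {format!r}")
    lines = [ln for ln in source.splitlines() if ln.strip()]
    if not lines:
        raise ModelFormatError("empty model document")
    header = lines[0].split("\t")
    if header[0] != "taxon" or "|" not in header:
        raise ModelFormatError(
            "header must start with 'taxon' and contain a '|' marker column")
    sep = header.index("|")
    resources = header[1:sep]
    toxins = header[sep + 1:]
    width = len(header)
    taxa, food_rows, tox_rows = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != width:
            raise ModelFormatError(
                f"ragged row at line {lineno}: expected {width} cells, "
                f"got {len(cells)}")
        if cells[sep] != "|":
            raise ModelFormatError(
                f"line {lineno}: '|' marker expected in column {sep}")
        taxa.append(cells[0])
        food_rows.append(_parse_cells(cells[1:sep], lineno, offset=1))
        tox_rows.append(_parse_cells(cells[sep + 1:], lineno, offset=sep + 1))
    model = CRTModel(taxa, resources, toxins,
                     np.array(food_rows, dtype=np.int8).reshape(len(taxa),
                                                                len(resources)),
                     np.array(tox_rows, dtype=np.int8).reshape(len(taxa),
                                                               len(toxins)))
    _raise_on_violations(model)
    return model


def _parse_cells(cells: list[str], lineno: int, offset: int) -> list[int]:
    out = []
    for k, cell in enumerate(cells):
        try:
            out.append(_CHAR_TO_SIGN[cell])
        except KeyError:
            raise ModelFormatError(
                f"bad cell {cell!r} at (line {lineno}, column {offset + k})"
            ) from None
    return out


def _raise_on_violations(model: CRTModel) -> None:
    report = validate_model(model)
    if report:
        raise ModelFormatError("; ".join(report))


# -- random generation -----------------------------------------------------

def random_model(params: GenerationParams) -> CRTModel:
    """Generate a random CRT model.

    Each food cell is drawn independently (+ with ``p_food_produce``, - with
    ``p_food_require``); toxin cells analogously.  Cells are drawn row-major
    from a single seeded PCG64 stream, so a given seed yields the same model
    on every platform.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    u = rng.random((params.S, params.M))
    food = np.zeros((params.S, params.M), dtype=np.int8)
    food[u < params.p_food_produce] = 1
    food[(u >= params.p_food_produce)
         & (u < params.p_food_produce + params.p_food_require)] = -1
    v = rng.random((params.S, params.T))
    tox = np.zeros((params.S, params.T), dtype=np.int8)
    tox[v < params.p_toxin_produce] = 1
    tox[(v >= params.p_toxin_produce)
        & (v < params.p_toxin_produce + params.p_toxin_sensitive)] = -1
    taxa = [f"s{i+1}" for i in range(params.S)]
    resources = [f"f{a+1}" for a in range(params.M)]
    toxins = [f"t{b+1}" for b in range(params.T)]
    return CRTModel(taxa, resources, toxins, food, tox)
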