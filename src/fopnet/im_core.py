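"""Index matrices: predicate-gated routing tables for net transitions.

A transition's condition is an index matrix whose rows are labelled by the
transition's input places and whose columns by its output places.  Each cell
holds a named predicate; a token resident in the row's place may move to the
column's place exactly when that predicate evaluates true in the current
firing context.  Cells left unspecified default to the always-false
predicate, so an index matrix only ever *permits* movement it was explicitly
given.

Predicate evaluation is read-only by contract: an evaluator receives the
candidate token, the source and target place ids, the net and the current
tick, and must not mutate any of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Any, Callable

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type checkers
    from .gn_engine import GNet, Token


class StructuralError(ValueError):
    """A net, matrix or configuration violates a structural invariant."""


class EvaluationError(RuntimeError):
    """A predicate evaluator raised; carries (row, col, predicate id)."""


#: evaluator signature: (token, source place id, target place id, net, tick) -> bool
Evaluator = Callable[["Token", str, str, "GNet", int], bool]


@dataclass(frozen=True)
class PredicateRef:
    """A named boolean condition attached to an index-matrix cell.

    ``id`` is a short symbol, ``description`` the human-readable meaning
    (for the bundled physiological net these are the phrases of the
    predicates, e.g. "the strength of the impact is greater than the
    threshold of the k-th receptor/sensor").
    """

    id: str
    description: str
    evaluator: Evaluator

    def __call__(self, token: "Token", src: str, dst: str, net: "GNet", tick: int) -> bool:
        return bool(self.evaluator(token, src, dst, net, tick))


ALWAYS_TRUE = PredicateRef("ALWAYS_TRUE", "always true", lambda tok, src, dst, net, tick: True)
ALWAYS_FALSE = PredicateRef("ALWAYS_FALSE", "always false", lambda tok, src, dst, net, tick: False)


@dataclass(frozen=True)
class FiringContext:
    """Everything a predicate may look at while a transition fires."""

    token: "Token"
    source_place: str
    net: "GNet"
    tick: int


class IndexMatrix:
    """Predicate matrix indexed by input-place (rows) and output-place (cols)."""

    def __init__(
        self,
        row_labels: list[str],
        col_labels: list[str],
        entries: dict[tuple[str, str], PredicateRef],
    ) -> None:
        self.row_labels = list(row_labels)
        self.col_labels = list(col_labels)
        self._entries = dict(entries)

    def predicate(self, row: str, col: str) -> PredicateRef:
        """Cell lookup; unspecified cells are ALWAYS_FALSE."""
        if row not in self._entries_rows():
            raise StructuralError(f"unknown row label {row!r}")
        if col not in self.col_labels:
            raise StructuralError(f"unknown column label {col!r}")
        return self._entries.get((row, col), ALWAYS_FALSE)

    def _entries_rows(self) -> list[str]:
        return self.row_labels

    def cells(self) -> dict[tuple[str, str], PredicateRef]:
        """All explicitly specified cells (defaults excluded)."""
        return dict(self._entries)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"IndexMatrix(rows={self.row_labels}, cols={self.col_labels}, n_cells={len(self._entries)})"


def _check_labels(labels: list[str], axis: str) -> None:
    if not labels:
        raise StructuralError(f"{axis} labels must be non-empty")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise StructuralError(f"duplicate label {lab}")
        seen.add(lab)


def make_index_matrix(
    rows: list[str],
    cols: list[str],
    entries: list[tuple[str, str, PredicateRef]],
) -> IndexMatrix:
    """Build an index matrix from a sparse cell list.

    Parameters
    ----------
    rows, cols:
        Duplicate-free, non-empty place-id lists (the transition's inputs
        and outputs, in declared order).
    entries:
        Sparse ``(row, col, predicate)`` triples; omitted cells default to
        :data:`ALWAYS_FALSE`.
    """
    _check_labels(rows, "row")
    _check_labels(cols, "column")
    cells: dict[tuple[str, str], PredicateRef] = {}
    for row, col, pred in entries:
        if row not in rows:
            raise StructuralError(f"entry references unknown row label {row!r}")
        if col not in cols:
            raise StructuralError(f"entry references unknown column label {col!r}")
        if not isinstance(pred, PredicateRef):
            raise StructuralError(f"cell ({row},{col}) is not a PredicateRef")
        cells[(row, col)] = pred
    return IndexMatrix(rows, cols, cells)


def im_evaluate_row(
    im: IndexMatrix, row: str, ctx: FiringContext
) -> list[tuple[str, bool]]:
    """Evaluate one row of the condition against a firing context.

    Returns one ``(column, enabled)`` pair per column, in declared column
    order — the same order a routing policy uses to break ties.  The
    context is not modified.
    """
    if row not in im.row_labels:
        raise StructuralError(f"unknown row label {row!r}")
    out: list[tuple[str, bool]] = []
    for col in im.col_labels:
        pred = im.predicate(row, col)
        try:
            enabled = bool(pred.evaluator(ctx.token, row, col, ctx.net, ctx.tick))
        except Exception as exc:  # noqa: BLE001 - wrapped with cell identity
            raise EvaluationError(
                f"predicate {pred.id!r} at cell ({row},{col}) raised: {exc!r}"
            ) from exc
        out.append((col, enabled))
    return out
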