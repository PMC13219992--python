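"""Atom selection mini-language.

Grammar (case-insensitive keywords, whitespace separated)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := not_expr ( "and" not_expr )*
    not_expr := "not" not_expr | "(" expr ")" | term
    term     := "all" | "none" | "protein" | "ligand" | "heavy" | "hydrogen"
              | "name" args | "element" args | "resname" args
              | "chain" args | "resid" ranges

``args`` is one or more identifiers (space- or comma-separated); ``ranges``
accepts integers and inclusive spans like ``60-69``. Resolution against a
fixed topology is deterministic and returns a sorted index tuple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SelectionError
from .io import Topology

_RESERVED = {"and", "or", "not", "(", ")"}
_NULLARY = {"all", "none", "protein", "ligand", "heavy", "hydrogen"}
_UNARY = {"name", "element", "resname", "chain", "resid"}


@dataclass(frozen=True)
class AtomSelection:
    """A selection expression and its resolved atom indices."""

    expression: str
    resolved: tuple[int, ...]

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.resolved, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.resolved)


def _tokenize(expression: str) -> list[str]:
    out = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        for piece in raw.split(","):
            if piece:
                out.append(piece)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topo: Topology):
        self.tokens = tokens
        self.pos = 0
        self.topo = topo

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok is not None and tok.lower() == "not":
            self.next()
            return ~self.not_expr()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.term()

    def term(self) -> np.ndarray:
        tok = self.next().lower()
        topo = self.topo
        if tok in _NULLARY:
            if tok == "all":
                return np.ones(topo.n_atoms, dtype=bool)
            if tok == "none":
                return np.zeros(topo.n_atoms, dtype=bool)
            if tok == "protein":
                return topo.protein_mask.copy()
            if tok == "ligand":
                return topo.is_ligand.copy()
            if tok == "heavy":
                return topo.heavy_mask.copy()
            return topo.is_hydrogen.copy()
        if tok in _UNARY:
            args = self._args(tok)
            if tok == "name":
                return np.isin(topo.names, args)
            if tok == "element":
                return np.isin(np.char.upper(topo.elements), [a.upper() for a in args])
            if tok == "resname":
                return np.isin(topo.res_names, args)
            if tok == "chain":
                return np.isin(topo.chain_ids, args)
            mask = np.zeros(topo.n_atoms, dtype=bool)
            for lo, hi in self._ranges(args):
                mask |= (topo.res_seqs >= lo) & (topo.res_seqs <= hi)
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")

    def _args(self, keyword: str) -> list[str]:
        args = []
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in _RESERVED | _NULLARY | _UNARY:
                break
            args.append(self.next())
        if not args:
            raise SelectionError(f"{keyword!r} requires at least one argument")
        return args

    @staticmethod
    def _ranges(args: list[str]) -> list[tuple[int, int]]:
        spans = []
        for a in args:
            try:
                if "-" in a[1:]:  # allow a leading minus sign
                    lo_s, hi_s = a[1:].split("-", 1)
                    lo, hi = int(a[0] + lo_s), int(hi_s)
                else:
                    lo = hi = int(a)
            except ValueError:
                raise SelectionError(f"bad resid range {a!r}") from None
            spans.append((lo, hi))
        return spans


def select_atoms(topology: Topology, expression: str) -> AtomSelection:
    """Resolve a selection expression against a topology.

    Empty results are legal (the caller decides whether that is an error);
    a malformed expression raises :class:`SelectionError`.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    return AtomSelection(expression, tuple(int(i) for i in np.nonzero(mask)[0]))
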