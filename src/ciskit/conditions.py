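"""Boolean conditions over feature tracks.

Conditions are expression trees whose leaves test a single base position
or a single region against the contents of other tracks, and whose inner
nodes are AND / OR / NOT.  The same tree can be built programmatically
or parsed from the concrete syntax used in protocol scripts, e.g.::

    avg(conservation) >= 0.3 and not overlaps(repeats)

Evaluation is a pure function of (condition, track environment, locus).
A locus is either an integer position or a :class:`~ciskit.core.Region`;
using a region predicate at a position (or vice versa) is an error.
"""

from __future__ import annotations

import re
from typing import Optional, Union

import numpy as np

from .core import CiskitError, DNATrack, NumericMap, NumericTrack, Region, RegionTrack

_OPS = {
    ">": np.greater, ">=": np.greater_equal,
    "<": np.less, "<=": np.less_equal,
    "=": np.equal, "==": np.equal, "!=": np.not_equal,
}

Locus = Union[int, Region]


class Condition:
    context = "any"  # 'position', 'region' or 'any'

    def evaluate(self, env, seq_name: str, locus: Locus) -> bool:
        raise NotImplementedError

    def text(self) -> str:
        raise NotImplementedError

    def __and__(self, other): return And(self, other)
    def __or__(self, other): return Or(self, other)
    def __invert__(self): return Not(self)


def _resolve(env, ref):
    """Resolve a track reference: already-a-track, or a name in env."""
    if isinstance(ref, str):
        obj = env.get(ref) if hasattr(env, "get") else env[ref]
        if obj is None:
            raise CiskitError(f"condition refers to unknown track {ref!r}")
        return obj
    return ref


def _require_position(locus) -> int:
    if isinstance(locus, Region):
        raise CiskitError("position predicate evaluated on a region")
    return int(locus)


def _require_region(locus) -> Region:
    if not isinstance(locus, Region):
        raise CiskitError("region predicate evaluated on a position")
    return locus


class TrueCondition(Condition):
    def evaluate(self, env, seq_name, locus):  # noqa: ARG002
        return True

    def text(self):
        return "true"


class And(Condition):
    def __init__(self, *parts):
        self.parts = parts

    def evaluate(self, env, seq_name, locus):
        return all(p.evaluate(env, seq_name, locus) for p in self.parts)

    def text(self):
        return "(" + " and ".join(p.text() for p in self.parts) + ")"


class Or(Condition):
    def __init__(self, *parts):
        self.parts = parts

    def evaluate(self, env, seq_name, locus):
        return any(p.evaluate(env, seq_name, locus) for p in self.parts)

    def text(self):
        return "(" + " or ".join(p.text() for p in self.parts) + ")"


class Not(Condition):
    def __init__(self, part):
        self.part = part

    def evaluate(self, env, seq_name, locus):
        return not self.part.evaluate(env, seq_name, locus)

    def text(self):
        return f"not {self.part.text()}"


# ---------------------------------------------------------------- position

class NumericCompare(Condition):
    """value of a numeric track at the position  <op>  operand.

    Operand may be a constant, another numeric track, or a per-sequence
    numeric map (broadcast over the sequence).
    """

    context = "position"

    def __init__(self, track, op: str, operand):
        if op not in _OPS:
            raise CiskitError(f"unknown comparison operator {op!r}")
        self.track, self.op, self.operand = track, op, operand

    def evaluate(self, env, seq_name, locus):
        pos = _require_position(locus)
        track = _resolve(env, self.track)
        value = track[seq_name][pos]
        operand = self.operand
        if isinstance(operand, str):
            operand = _resolve(env, operand)
        if isinstance(operand, NumericTrack):
            operand = operand[seq_name][pos]
        elif isinstance(operand, NumericMap):
            operand = operand[seq_name]
        return bool(_OPS[self.op](value, operand))

    def text(self):
        op = self.operand if isinstance(self.operand, str) else repr(self.operand)
        return f"value({self._name(self.track)}) {self.op} {op}"

    @staticmethod
    def _name(ref):
        return ref if isinstance(ref, str) else "<track>"


class Inside(Condition):
    """True at positions covered by at least one region of the track."""

    context = "position"

    def __init__(self, track):
        self.track = track

    def evaluate(self, env, seq_name, locus):
        pos = _require_position(locus)
        track = _resolve(env, self.track)
        return any(r.start <= pos < r.end for r in track[seq_name])

    def text(self):
        return f"inside({NumericCompare._name(self.track)})"


class BaseIn(Condition):
    """True where the DNA letter (upper-cased) is in the given set."""

    context = "position"

    def __init__(self, track, bases):
        self.track = track
        self.bases = {b.upper() for b in bases}

    def evaluate(self, env, seq_name, locus):
        pos = _require_position(locus)
        track = _resolve(env, self.track)
        return track[seq_name][pos].upper() in self.bases

    def text(self):
        return f"base({NumericCompare._name(self.track)}) in {{{','.join(sorted(self.bases))}}}"


# ------------------------------------------------------------------ region

class RegionCompare(Condition):
    """Test a region attribute (length or score) against a constant."""

    context = "region"

    def __init__(self, attr: str, op: str, value: float):
        if attr not in ("length", "score"):
            raise CiskitError(f"unknown region attribute {attr!r}")
        self.attr, self.op, self.value = attr, op, value

    def evaluate(self, env, seq_name, locus):
        region = _require_region(locus)
        got = region.length if self.attr == "length" else region.score
        return bool(_OPS[self.op](got, self.value))

    def text(self):
        return f"{self.attr} {self.op} {self.value!r}"


class TypeIs(Condition):
    context = "region"

    def __init__(self, types):
        self.types = {types} if isinstance(types, str) else set(types)

    def evaluate(self, env, seq_name, locus):
        return _require_region(locus).type in self.types

    def text(self):
        return f"type in {{{','.join(sorted(self.types))}}}"


class Overlaps(Condition):
    """True for regions overlapping >= 1 region of another track."""

    context = "region"

    def __init__(self, track):
        self.track = track

    def evaluate(self, env, seq_name, locus):
        region = _require_region(locus)
        track = _resolve(env, self.track)
        return any(r.start < region.end and region.start < r.end
                   for r in track[seq_name])

    def text(self):
        return f"overlaps({NumericCompare._name(self.track)})"


class AvgWithin(Condition):
    """Arithmetic mean of a numeric track over the region's half-open
    span, compared against a constant."""

    context = "region"

    def __init__(self, track, op: str, value: float):
        self.track, self.op, self.value = track, op, value

    def evaluate(self, env, seq_name, locus):
        region = _require_region(locus)
        track = _resolve(env, self.track)
        mean = float(np.mean(track[seq_name][region.start:region.end]))
        return bool(_OPS[self.op](mean, self.value))

    def text(self):
        return f"avg({NumericCompare._name(self.track)}) {self.op} {self.value!r}"


def nearest_edge_gap(a: Region, b: Region) -> int:
    """Gap between closest edges of two regions; 0 when they overlap."""
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end)


class DistanceToNearest(Condition):
    """True when the nearest-edge gap to some region of another track is
    <= d (the region itself is not its own neighbour)."""

    context = "region"

    def __init__(self, track, max_distance: int):
        self.track, self.max_distance = track, max_distance

    def evaluate(self, env, seq_name, locus):
        region = _require_region(locus)
        track = _resolve(env, self.track)
        for r in track[seq_name]:
            if r is region:
                continue
            if nearest_edge_gap(region, r) <= self.max_distance:
                return True
        return False

    def text(self):
        return f"distance({NumericCompare._name(self.track)}) <= {self.max_distance!r}"


def eval_condition(cond: Condition, env, seq_name: str, locus: Locus) -> bool:
    """Evaluate a condition at a position (int) or region.

    ``env`` is any mapping from track names to tracks (a Repository or a
    plain dict); already-materialized tracks inside the condition are
    used as-is.
    """
    return cond.evaluate(env, seq_name, locus)


# ---------------------------------------------------------------- parsing

_TOKEN_RE = re.compile(r"""
    \s*(?:
      (?P<lpar>\() | (?P<rpar>\)) |
      (?P<op><=|>=|==|!=|<|>|=) |
      (?P<number>-?\d+\.?\d*(?:[eE][-+]?\d+)?) |
      (?P<set>\{[^}]*\}) |
      (?P<word>[A-Za-z_][A-Za-z0-9_]*)
    )""", re.VERBOSE)


def _tokenize(text: str):
    tokens, i = [], 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m or m.end() == i:
            if text[i:].strip():
                raise CiskitError(f"condition syntax error at column {i + 1}: {text[i:]!r}")
            break
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
        i = m.end()
    return tokens


class _Parser:
    """Recursive descent over: or-expr -> and-expr -> unary -> atom."""

    def __init__(self, tokens):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, kind, value=None):
        k, v = self.next()
        if k != kind or (value is not None and v != value):
            raise CiskitError(f"condition syntax error: expected {value or kind}, got {v!r}")
        return v

    def parse(self) -> Condition:
        cond = self.or_expr()
        if self.pos != len(self.tokens):
            raise CiskitError(f"condition syntax error: trailing {self.peek()[1]!r}")
        return cond

    def or_expr(self):
        left = self.and_expr()
        while self.peek() == ("word", "or"):
            self.next()
            left = Or(left, self.and_expr())
        return left

    def and_expr(self):
        left = self.unary()
        while self.peek() == ("word", "and"):
            self.next()
            left = And(left, self.unary())
        return left

    def unary(self):
        if self.peek() == ("word", "not"):
            self.next()
            return Not(self.unary())
        if self.peek()[0] == "lpar":
            self.next()
            cond = self.or_expr()
            self.expect("rpar")
            return cond
        return self.atom()

    def _comparison_tail(self):
        op = self.expect("op")
        kind, val = self.next()
        if kind == "number":
            return op, float(val)
        if kind == "word":
            return op, val
        raise CiskitError(f"condition syntax error: bad comparison operand {val!r}")

    def atom(self):
        kind, word = self.next()
        if kind != "word":
            raise CiskitError(f"condition syntax error: unexpected {word!r}")
        if word == "true":
            return TrueCondition()
        if word in ("inside", "overlaps", "avg", "value", "distance", "base", "length",
                    "score", "type"):
            if word in ("length", "score"):
                op, val = self._comparison_tail()
                return RegionCompare(word, op, val)
            if word == "type":
                self.expect("word", "in")
                kind, setlit = self.next()
                if kind != "set":
                    raise CiskitError("condition syntax error: type in {...} expected")
                return TypeIs({s.strip() for s in setlit[1:-1].split(",") if s.strip()})
            self.expect("lpar")
            ref = self.expect("word")
            self.expect("rpar")
            if word == "inside":
                return Inside(ref)
            if word == "overlaps":
                return Overlaps(ref)
            if word == "avg":
                op, val = self._comparison_tail()
                if not isinstance(val, float):
                    raise CiskitError("avg() must be compared against a number")
                return AvgWithin(ref, op, val)
            if word == "value":
                op, val = self._comparison_tail()
                return NumericCompare(ref, op, val)
            if word == "distance":
                op, val = self._comparison_tail()
                if op != "<=":
                    raise CiskitError("distance() supports only <=")
                return DistanceToNearest(ref, int(val))
            if word == "base":
                self.expect("word", "in")
                kind, setlit = self.next()
                if kind != "set":
                    raise CiskitError("condition syntax error: base(...) in {...} expected")
                return BaseIn(ref, {s.strip() for s in setlit[1:-1].split(",") if s.strip()})
        # bare track name: value(track) shorthand
        op, val = self._comparison_tail()
        return NumericCompare(word, op, val)


def parse_condition(text: str) -> Condition:
    """Parse the concrete condition syntax used in protocol scripts."""
    return _Parser(_tokenize(text)).parse()
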