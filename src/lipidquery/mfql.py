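"""The molecular fragmentation query language (MFQL).

MFQL formalizes lipid fragmentation knowledge as declarative queries that
probe a MasterScan.  A query has four sections::

    QUERYNAME = Phosphatidylcholine;
    DEFINE headPC = 'C5 H15 O4 N1 P1' WITH CHG = +1;
    DEFINE prPC = 'C[30..48]H[30..200]N[1]O[8]P[1]' WITH CHG = +1, DBR = (1.5, 7.5);
    IDENTIFY prPC IN MS1+ AND headPC IN MS2+
    SUCHTHAT isEven(prPC.chemsc[C])
    REPORT MASS = prPC.mass;
           NAME = "PC [%d:%d]" % "((prPC.chemsc - headPC.chemsc)[C] - 3, prPC.chemsc[db] - 1.5)";
           ...

DEFINE binds names to explicit sum compositions, bracket-range
sc-constraints, masses or mass lists; IDENTIFY places the variables in MS1
or MS2 spectra of either polarity, combined with AND/OR; SUCHTHAT filters
candidate bindings with arithmetic/boolean expressions over peak attributes
(.mass, .chemsc, .chemsc[C], .chemsc[db], .errppm, .intensity, .occupation);
REPORT defines the output columns, including the two-string ``"fmt" %
"(args)"`` formatting idiom.

The grammar here (tokenizer + recursive-descent parser) is the normative
dialect of this package, reconstructed from the published worked queries;
it is documented in docs/mfql.md.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chem
from .chem import (
    SCConstraint,
    SumComposition,
    Tolerance,
    dbr,
    enumerate_compositions,
    monoisotopic_mz,
    parse_sc_constraint,
    parse_sum_composition,
)
from .masterscan import FragmentEntry, MasterScan, PrecursorEntry

__all__ = [
    "MfqlSyntaxError",
    "MfqlEvalError",
    "MfqlQuery",
    "VariableBinding",
    "ReportRow",
    "parse_mfql",
    "evaluate",
    "evaluate_report_expression",
    "run_queries",
]


class MfqlSyntaxError(ValueError):
    def __init__(self, message: str, line: int = 0, column: int = 0):
        super().__init__(f"line {line}, column {column}: {message}" if line else message)
        self.line = line
        self.column = column


class MfqlEvalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# lexer

_KEYWORDS = {
    "QUERYNAME", "DEFINE", "IDENTIFY", "SUCHTHAT", "REPORT",
    "WITH", "CHG", "DBR", "AND", "OR", "NOT", "IN", "MS1", "MS2",
}

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>\#[^\n]*)
  | (?P<number>\d+\.\d*|\.\d+|\d+)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<sq>'[^']*')
  | (?P<dq>"[^"]*")
  | (?P<op><=|>=|==|!=|[-+*/%<>=(),;\[\].])
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class Token:
    kind: str  # KEYWORD NAME NUMBER SQSTRING DQSTRING OP EOF
    value: str
    line: int
    column: int


def _tokenize(text: str) -> list[Token]:
    tokens = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise MfqlSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        value = m.group()
        if kind not in ("ws", "comment"):
            if kind == "name" and value.upper() in _KEYWORDS:
                tokens.append(Token("KEYWORD", value.upper(), line, col))
            elif kind == "name":
                tokens.append(Token("NAME", value, line, col))
            elif kind == "number":
                tokens.append(Token("NUMBER", value, line, col))
            elif kind == "sq":
                tokens.append(Token("SQSTRING", value[1:-1], line, col))
            elif kind == "dq":
                tokens.append(Token("DQSTRING", value[1:-1], line, col))
            else:
                tokens.append(Token("OP", value, line, col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(Token("EOF", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# AST

@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Str:
    value: str


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Attr:
    obj: "Expr"
    name: str


@dataclass(frozen=True)
class Index:
    obj: "Expr"
    key: str


@dataclass(frozen=True)
class BinOp:
    op: str
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class UnaryOp:
    op: str
    operand: "Expr"


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple["Expr", ...]


@dataclass(frozen=True)
class Format:
    fmt: str
    args: tuple["Expr", ...]


Expr = Num | Str | Var | Attr | Index | BinOp | UnaryOp | Call | Format


@dataclass(frozen=True)
class Definition:
    """One DEFINE binding: composition, sc-constraint, mass or mass list."""

    name: str
    body: SumComposition | SCConstraint | float | tuple[float, ...]


@dataclass(frozen=True)
class IdentifyClause:
    variable: str
    level: int          # 1 | 2
    polarity: str       # '+' | '-'


@dataclass(frozen=True)
class IdentifyExpr:
    """Boolean combination of IDENTIFY clauses (left-assoc AND/OR tree)."""

    op: str | None                      # None for a leaf
    clause: IdentifyClause | None = None
    left: "IdentifyExpr | None" = None
    right: "IdentifyExpr | None" = None

    def clauses(self) -> list[IdentifyClause]:
        if self.clause is not None:
            return [self.clause]
        return self.left.clauses() + self.right.clauses()

    def satisfied(self, bound: dict[str, bool]) -> bool:
        if self.clause is not None:
            return bound.get(self.clause.variable, False)
        l = self.left.satisfied(bound)
        r = self.right.satisfied(bound)
        return (l and r) if self.op == "AND" else (l or r)


@dataclass(frozen=True)
class MfqlQuery:
    name: str
    defines: dict[str, Definition]
    identify: IdentifyExpr
    suchthat: Expr | None
    report: tuple[tuple[str, Expr], ...]
    source: str = ""


# ---------------------------------------------------------------------------
# parser

class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def tok(self) -> Token:
        return self.tokens[self.i]

    def _advance(self) -> Token:
        t = self.tok
        self.i += 1
        return t

    def _expect(self, kind: str, value: str | None = None) -> Token:
        t = self.tok
        if t.kind != kind or (value is not None and t.value != value):
            want = value or kind
            raise MfqlSyntaxError(f"expected {want!r}, found {t.value!r}", t.line, t.column)
        return self._advance()

    def _accept(self, kind: str, value: str | None = None) -> Token | None:
        t = self.tok
        if t.kind == kind and (value is None or t.value == value):
            return self._advance()
        return None

    def _skip_semicolons(self):
        while self._accept("OP", ";"):
            pass

    # ---- query structure

    def parse_query(self) -> MfqlQuery:
        self._expect("KEYWORD", "QUERYNAME")
        self._expect("OP", "=")
        name = self._expect("NAME").value
        self._skip_semicolons()

        defines: dict[str, Definition] = {}
        identify: IdentifyExpr | None = None
        suchthat: Expr | None = None
        report: list[tuple[str, Expr]] = []

        while self.tok.kind != "EOF":
            t = self.tok
            if t.kind != "KEYWORD":
                raise MfqlSyntaxError(
                    f"expected a section keyword, found {t.value!r}", t.line, t.column
                )
            if t.value == "DEFINE":
                self._advance()
                while self.tok.kind == "NAME":
                    d = self._parse_define()
                    if d.name in defines:
                        raise MfqlSyntaxError(f"variable {d.name!r} defined twice",
                                              t.line, t.column)
                    defines[d.name] = d
                    self._skip_semicolons()
            elif t.value == "IDENTIFY":
                self._advance()
                identify = self._parse_identify()
                self._skip_semicolons()
            elif t.value == "SUCHTHAT":
                self._advance()
                suchthat = self._parse_expr()
                self._skip_semicolons()
            elif t.value == "REPORT":
                self._advance()
                while self.tok.kind == "NAME":
                    col = self._expect("NAME").value
                    self._expect("OP", "=")
                    report.append((col, self._parse_expr()))
                    self._skip_semicolons()
            else:
                raise MfqlSyntaxError(f"unexpected keyword {t.value}", t.line, t.column)

        if identify is None:
            raise MfqlSyntaxError("query lacks an IDENTIFY section")
        if not report:
            raise MfqlSyntaxError("query lacks a REPORT section")

        query = MfqlQuery(name, defines, identify, suchthat, tuple(report))
        self._check_variables(query)
        return query

    def _parse_define(self) -> Definition:
        name = self._expect("NAME").value
        self._expect("OP", "=")
        t = self.tok
        charge = 0
        dbr_range: tuple[float, float] | None = None
        if t.kind == "SQSTRING":
            self._advance()
            body_text = t.value
        elif t.kind == "NUMBER":
            self._advance()
            body_text = None
            body: float | tuple[float, ...] = float(t.value)
        elif t.kind == "OP" and t.value == "(":
            self._advance()
            masses = [float(self._expect("NUMBER").value)]
            while self._accept("OP", ","):
                masses.append(float(self._expect("NUMBER").value))
            self._expect("OP", ")")
            body_text = None
            body = tuple(masses)
        else:
            raise MfqlSyntaxError(
                f"expected a quoted formula, mass or mass list, found {t.value!r}",
                t.line, t.column,
            )
        if self._accept("KEYWORD", "WITH"):
            while True:
                kw = self.tok
                if self._accept("KEYWORD", "CHG"):
                    self._expect("OP", "=")
                    sign = 1
                    if self._accept("OP", "+"):
                        sign = 1
                    elif self._accept("OP", "-"):
                        sign = -1
                    charge = sign * int(self._expect("NUMBER").value)
                elif self._accept("KEYWORD", "DBR"):
                    self._expect("OP", "=")
                    self._expect("OP", "(")
                    lo = self._parse_signed_number()
                    self._expect("OP", ",")
                    hi = self._parse_signed_number()
                    self._expect("OP", ")")
                    dbr_range = (lo, hi)
                else:
                    raise MfqlSyntaxError(
                        f"expected CHG or DBR, found {kw.value!r}", kw.line, kw.column
                    )
                if not self._accept("OP", ","):
                    break
        if body_text is not None:
            if "[" in body_text:
                body = parse_sc_constraint(
                    body_text, charge, dbr_range or (-float("inf"), float("inf"))
                )
            else:
                sc = parse_sum_composition(body_text)
                body = SumComposition(sc.counts, charge)
        return Definition(name, body)

    def _parse_signed_number(self) -> float:
        sign = 1.0
        if self._accept("OP", "-"):
            sign = -1.0
        elif self._accept("OP", "+"):
            sign = 1.0
        return sign * float(self._expect("NUMBER").value)

    def _parse_identify(self) -> IdentifyExpr:
        left = self._parse_identify_clause()
        while True:
            t = self.tok
            if t.kind == "KEYWORD" and t.value in ("AND", "OR"):
                self._advance()
                right = self._parse_identify_clause()
                left = IdentifyExpr(t.value, None, left, right)
            else:
                return left

    def _parse_identify_clause(self) -> IdentifyExpr:
        var = self._expect("NAME").value
        self._expect("KEYWORD", "IN")
        t = self.tok
        if self._accept("KEYWORD", "MS1"):
            level = 1
        elif self._accept("KEYWORD", "MS2"):
            level = 2
        else:
            raise MfqlSyntaxError(f"expected MS1 or MS2, found {t.value!r}",
                                  t.line, t.column)
        if self._accept("OP", "+"):
            pol = "+"
        elif self._accept("OP", "-"):
            pol = "-"
        else:
            raise MfqlSyntaxError("spectrum level needs a polarity sign (+/-)",
                                  self.tok.line, self.tok.column)
        return IdentifyExpr(None, IdentifyClause(var, level, pol))

    # ---- expressions (precedence: or < and < not < comparison < add < mul < unary < postfix)

    def _parse_expr(self) -> Expr:
        return self._parse_or()

    def _parse_or(self) -> Expr:
        left = self._parse_and()
        while self._accept("KEYWORD", "OR"):
            left = BinOp("OR", left, self._parse_and())
        return left

    def _parse_and(self) -> Expr:
        left = self._parse_not()
        while self._accept("KEYWORD", "AND"):
            left = BinOp("AND", left, self._parse_not())
        return left

    def _parse_not(self) -> Expr:
        if self._accept("KEYWORD", "NOT"):
            return UnaryOp("NOT", self._parse_not())
        return self._parse_comparison()

    def _parse_comparison(self) -> Expr:
        left = self._parse_additive()
        t = self.tok
        if t.kind == "OP" and t.value in ("<", "<=", ">", ">=", "==", "!="):
            self._advance()
            right = self._parse_additive()
            return BinOp(t.value, left, right)
        return left

    def _parse_additive(self) -> Expr:
        left = self._parse_multiplicative()
        while True:
            t = self.tok
            if t.kind == "OP" and t.value in ("+", "-"):
                self._advance()
                left = BinOp(t.value, left, self._parse_multiplicative())
            else:
                return left

    def _parse_multiplicative(self) -> Expr:
        left = self._parse_unary()
        while True:
            t = self.tok
            if t.kind == "OP" and t.value in ("*", "/"):
                self._advance()
                left = BinOp(t.value, left, self._parse_unary())
            else:
                return left

    def _parse_unary(self) -> Expr:
        if self._accept("OP", "-"):
            return UnaryOp("-", self._parse_unary())
        if self._accept("OP", "+"):
            return self._parse_unary()
        return self._parse_postfix()

    def _parse_postfix(self) -> Expr:
        node = self._parse_primary()
        while True:
            if self._accept("OP", "."):
                node = Attr(node, self._expect("NAME").value)
            elif self._accept("OP", "["):
                t = self.tok
                if t.kind == "NAME":
                    self._advance()
                    key = t.value
                else:
                    raise MfqlSyntaxError(
                        f"expected an element symbol or 'db', found {t.value!r}",
                        t.line, t.column,
                    )
                self._expect("OP", "]")
                node = Index(node, key)
            else:
                return node

    def _parse_primary(self) -> Expr:
        t = self.tok
        if t.kind == "NUMBER":
            self._advance()
            return Num(float(t.value))
        if t.kind == "DQSTRING":
            self._advance()
            if self._accept("OP", "%"):
                args_tok = self._expect("DQSTRING")
                args = _parse_format_args(args_tok.value, args_tok.line, args_tok.column)
                return Format(t.value, args)
            return Str(t.value)
        if t.kind == "SQSTRING":
            self._advance()
            return Str(t.value)
        if t.kind == "NAME":
            self._advance()
            if self._accept("OP", "("):
                args = []
                if not (self.tok.kind == "OP" and self.tok.value == ")"):
                    args.append(self._parse_expr())
                    while self._accept("OP", ","):
                        args.append(self._parse_expr())
                self._expect("OP", ")")
                return Call(t.value, tuple(args))
            return Var(t.value)
        if t.kind == "OP" and t.value == "(":
            self._advance()
            node = self._parse_expr()
            self._expect("OP", ")")
            return node
        raise MfqlSyntaxError(f"unexpected token {t.value!r}", t.line, t.column)

    # ---- static checks

    def _check_variables(self, query: MfqlQuery) -> None:
        defined = set(query.defines)
        for clause in query.identify.clauses():
            if clause.variable not in defined:
                raise MfqlSyntaxError(
                    f"IDENTIFY references undefined variable {clause.variable!r}"
                )

        def walk(e: Expr):
            if isinstance(e, Var):
                if e.name not in defined:
                    raise MfqlSyntaxError(f"undefined variable {e.name!r}")
            elif isinstance(e, (Attr,)):
                walk(e.obj)
            elif isinstance(e, Index):
                walk(e.obj)
            elif isinstance(e, BinOp):
                walk(e.left)
                walk(e.right)
            elif isinstance(e, UnaryOp):
                walk(e.operand)
            elif isinstance(e, (Call, Format)):
                for a in e.args:
                    walk(a)

        if query.suchthat is not None:
            walk(query.suchthat)
        for _, expr in query.report:
            walk(expr)


def _parse_format_args(text: str, line: int, column: int) -> tuple[Expr, ...]:
    """Parse the second string of the ``"fmt" % "(a, b, ...)"`` idiom."""
    tokens = _tokenize(text)
    p = _Parser(tokens)
    p._expect("OP", "(")
    args = [p._parse_expr()]
    while p._accept("OP", ","):
        args.append(p._parse_expr())
    p._expect("OP", ")")
    if p.tok.kind != "EOF":
        raise MfqlSyntaxError("trailing content in format arguments", line, column)
    return tuple(args)


def parse_mfql(text: str) -> MfqlQuery:
    """Parse one MFQL query text into its AST."""
    query = _Parser(_tokenize(text)).parse_query()
    return MfqlQuery(query.name, query.defines, query.identify, query.suchthat,
                     query.report, source=text)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class VariableBinding:
    """One candidate match of a DEFINEd variable to a MasterScan peak."""

    variable: str
    entry: PrecursorEntry | FragmentEntry
    chemsc: SumComposition | None
    theoretical_mz: float
    ambiguous: bool = False

    @property
    def mass(self) -> float:
        return self.entry.mz

    @property
    def err_da(self) -> float:
        return self.entry.mz - self.theoretical_mz

    @property
    def errppm(self) -> float:
        return (self.entry.mz - self.theoretical_mz) / self.theoretical_mz * 1e6

    @property
    def intensity(self) -> np.ndarray:
        return self.entry.intensities

    @property
    def occupation(self) -> float:
        return self.entry.occupancy


@dataclass
class ReportRow:
    query: str
    precursor_mz: float
    columns: dict[str, object]


def _candidates_ms1(
    defn: Definition, entry: PrecursorEntry, tol: Tolerance, polarity: str
) -> list[VariableBinding]:
    out: list[VariableBinding] = []
    body = defn.body
    if isinstance(body, SCConstraint):
        if (body.charge > 0) != (polarity == "+") and body.charge != 0:
            return []
        matches = enumerate_compositions(body, entry.mz, tol)
        for sc in matches:
            out.append(
                VariableBinding(defn.name, entry, sc, monoisotopic_mz(sc),
                                ambiguous=len(matches) > 1)
            )
    elif isinstance(body, SumComposition):
        target = monoisotopic_mz(body)
        if tol.matches(entry.mz, target):
            out.append(VariableBinding(defn.name, entry, body, target))
    elif isinstance(body, float):
        if tol.matches(entry.mz, body):
            out.append(VariableBinding(defn.name, entry, None, body))
    else:  # mass list
        for m in body:
            if tol.matches(entry.mz, m):
                out.append(VariableBinding(defn.name, entry, None, m))
    return out


def _candidates_ms2(
    defn: Definition, entry: PrecursorEntry, tol: Tolerance, polarity: str
) -> list[VariableBinding]:
    out: list[VariableBinding] = []
    body = defn.body
    for frag in entry.msms:
        if isinstance(body, SCConstraint):
            matches = enumerate_compositions(body, frag.mz, tol)
            for sc in matches:
                out.append(
                    VariableBinding(defn.name, frag, sc, monoisotopic_mz(sc),
                                    ambiguous=len(matches) > 1)
                )
        elif isinstance(body, SumComposition):
            target = monoisotopic_mz(body)
            if tol.matches(frag.mz, target):
                out.append(VariableBinding(defn.name, frag, body, target))
        elif isinstance(body, float):
            if tol.matches(frag.mz, body):
                out.append(VariableBinding(defn.name, frag, None, body))
        else:
            for m in body:
                if tol.matches(frag.mz, m):
                    out.append(VariableBinding(defn.name, frag, None, m))
    return out


_FUNCTIONS = {
    "isEven": lambda x: float(x) == int(x) and int(x) % 2 == 0,
    "isOdd": lambda x: float(x) == int(x) and int(x) % 2 == 1,
    "abs": abs,
}


def _eval_expr(expr: Expr, bindings: dict[str, VariableBinding]) -> object:
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Str):
        return expr.value
    if isinstance(expr, Var):
        if expr.name not in bindings:
            raise MfqlEvalError(f"variable {expr.name!r} is not bound")
        return bindings[expr.name]
    if isinstance(expr, Attr):
        obj = _eval_expr(expr.obj, bindings)
        if not isinstance(obj, VariableBinding):
            raise MfqlEvalError(f"attribute access on non-variable: .{expr.name}")
        if expr.name == "mass":
            return obj.mass
        if expr.name == "chemsc":
            if obj.chemsc is None:
                raise MfqlEvalError(
                    f"variable {obj.variable!r} has no bound sum composition"
                )
            return obj.chemsc
        if expr.name == "errppm":
            return obj.errppm
        if expr.name == "errda":
            return obj.err_da
        if expr.name == "intensity":
            return obj.intensity
        if expr.name == "occupation":
            return obj.occupation
        raise MfqlEvalError(f"unknown attribute {expr.name!r}")
    if isinstance(expr, Index):
        obj = _eval_expr(expr.obj, bindings)
        if isinstance(obj, VariableBinding):
            obj = obj.chemsc
        if not isinstance(obj, SumComposition):
            raise MfqlEvalError("indexing requires a sum composition")
        return obj[expr.key]
    if isinstance(expr, UnaryOp):
        val = _eval_expr(expr.operand, bindings)
        if expr.op == "NOT":
            return not bool(val)
        return -val
    if isinstance(expr, BinOp):
        if expr.op == "AND":
            return bool(_eval_expr(expr.left, bindings)) and bool(
                _eval_expr(expr.right, bindings)
            )
        if expr.op == "OR":
            return bool(_eval_expr(expr.left, bindings)) or bool(
                _eval_expr(expr.right, bindings)
            )
        left = _eval_expr(expr.left, bindings)
        right = _eval_expr(expr.right, bindings)
        if isinstance(left, VariableBinding):
            left = left.chemsc if isinstance(right, (SumComposition, VariableBinding)) else left.mass
        if isinstance(right, VariableBinding):
            right = right.chemsc if isinstance(left, SumComposition) else right.mass
        if expr.op == "+":
            return left + right
        if expr.op == "-":
            return left - right
        if expr.op == "*":
            return left * right
        if expr.op == "/":
            return left / right
        if expr.op == "<":
            return left < right
        if expr.op == "<=":
            return left <= right
        if expr.op == ">":
            return left > right
        if expr.op == ">=":
            return left >= right
        if expr.op == "==":
            return left == right
        if expr.op == "!=":
            return left != right
    if isinstance(expr, Call):
        if expr.func not in _FUNCTIONS:
            raise MfqlEvalError(f"unknown function {expr.func!r}")
        args = [_eval_expr(a, bindings) for a in expr.args]
        args = [a.mass if isinstance(a, VariableBinding) else a for a in args]
        return _FUNCTIONS[expr.func](*args)
    if isinstance(expr, Format):
        args = [_eval_expr(a, bindings) for a in expr.args]
        return _format(expr.fmt, args)
    raise MfqlEvalError(f"cannot evaluate {expr!r}")


_FMT_RE = re.compile(r"%(\.\d+)?[dfs]")


def _format(fmt: str, args: list[object]) -> str:
    """The two-string formatting idiom; %d truncates toward zero."""
    placeholders = _FMT_RE.findall(fmt)
    n = len(_FMT_RE.findall(fmt))
    if n != len(args):
        raise MfqlEvalError(
            f"format {fmt!r} expects {n} arguments, got {len(args)}"
        )
    it = iter(args)

    def sub(m: re.Match) -> str:
        spec = m.group(0)
        val = next(it)
        if spec.endswith("d"):
            return str(int(float(val)))  # truncation toward zero
        if spec.endswith("f"):
            prec = m.group(1)
            digits = int(prec[1:]) if prec else 1
            return f"{float(val):.{digits}f}"
        return str(val)

    return _FMT_RE.sub(sub, fmt)


def evaluate_report_expression(expr: Expr, bindings: dict[str, VariableBinding]) -> object:
    """Evaluate one REPORT column for a binding set."""
    value = _eval_expr(expr, bindings)
    if isinstance(value, VariableBinding):
        # bare variable in REPORT: the peak's mass
        value = value.mass
    if isinstance(value, SumComposition):
        value = str(value)
    return value


def evaluate(
    query: MfqlQuery,
    ms: MasterScan,
    tol_ms1: Tolerance | str | float = Tolerance(5.0, "ppm"),
    tol_ms2: Tolerance | str | float = Tolerance(0.3, "da"),
) -> list[ReportRow]:
    """Run one query against a MasterScan.

    For every precursor entry, MS1 variables are bound by composition
    enumeration (sc-constraints) or direct mass match within *tol_ms1*; MS2
    variables are matched within the entry's own fragment block within
    *tol_ms2* (so a fragment is only ever searched in MS/MS spectra of its
    candidate precursor).  AND requires all clauses bound, OR any; SUCHTHAT
    then filters candidate binding sets and REPORT produces one row per
    surviving set.  Extra unrelated fragments in a block never prevent a
    match.
    """
    tol1 = Tolerance.parse(tol_ms1)
    tol2 = Tolerance.parse(tol_ms2)
    clauses = query.identify.clauses()
    for c in clauses:
        if c.polarity != ms.polarity:
            return []
    ms1_vars = [c.variable for c in clauses if c.level == 1]
    ms2_vars = [c.variable for c in clauses if c.level == 2]

    rows: list[ReportRow] = []
    for entry in ms.entries:
        cand: dict[str, list[VariableBinding]] = {}
        for v in ms1_vars:
            cand[v] = _candidates_ms1(query.defines[v], entry, tol1, ms.polarity)
        for v in ms2_vars:
            cand[v] = _candidates_ms2(query.defines[v], entry, tol2, ms.polarity)

        pools = {
            v: (c if c else [None]) for v, c in cand.items()
        }
        names = list(pools)
        for combo in itertools.product(*(pools[v] for v in names)):
            bindings = {v: b for v, b in zip(names, combo) if b is not None}
            bound_flags = {v: (v in bindings) for v in names}
            if not query.identify.satisfied(bound_flags):
                continue
            if query.suchthat is not None:
                try:
                    if not bool(_eval_expr(query.suchthat, bindings)):
                        continue
                except MfqlEvalError:
                    continue  # unbound OR-branch variable in the filter
            try:
                columns = {
                    col: evaluate_report_expression(expr, bindings)
                    for col, expr in query.report
                }
            except MfqlEvalError:
                continue
            rows.append(ReportRow(query.name, entry.mz, columns))
    rows.sort(key=lambda r: (r.precursor_mz, str(r.columns.get("NAME", ""))))
    # drop exact duplicates (identical binding projections)
    unique: list[ReportRow] = []
    seen = set()
    for r in rows:
        key = (r.precursor_mz, tuple(
            (k, str(v)) for k, v in r.columns.items()
        ))
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return unique


def run_queries(
    queries: list[MfqlQuery],
    ms: MasterScan,
    output: str | Path | None = None,
    tol_ms1: Tolerance | str | float = Tolerance(5.0, "ppm"),
    tol_ms2: Tolerance | str | float = Tolerance(0.3, "da"),
):
    """Run queries and write one deterministic CSV report.

    Columns: QUERY, PRECURSOR_MZ, then the union of user-defined columns in
    first-seen order; per-acquisition intensity vectors expand into one
    column per acquisition id.  Returns the DataFrame.
    """
    import pandas as pd

    if not queries:
        raise ValueError("no queries")
    records = []
    columns: list[str] = ["QUERY", "PRECURSOR_MZ"]
    for q in queries:
        for row in evaluate(q, ms, tol_ms1, tol_ms2):
            rec = {"QUERY": row.query, "PRECURSOR_MZ": round(row.precursor_mz, 6)}
            for col, val in row.columns.items():
                if isinstance(val, np.ndarray):
                    for i, aid in enumerate(ms.acquisition_ids):
                        name = f"{col}:{aid}"
                        rec[name] = val[i]
                        if name not in columns:
                            columns.append(name)
                else:
                    rec[col] = val
                    if col not in columns:
                        columns.append(col)
            records.append(rec)
    frame = pd.DataFrame(records, columns=columns)
    if output is not None:
        frame.to_csv(output, index=False)
    return frame
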