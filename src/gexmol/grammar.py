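"""SMILES ↔ context-free-grammar production-rule sequences.

A molecule's canonical SMILES is parsed under a fixed CFG into its leftmost
derivation — an ordered sequence of production-rule indices — which in turn
is represented as a one-hot ``T × R`` matrix for the sequence models.
Decoding goes the other way: per-step rule logits are turned into a rule
sequence by *stack-masked* selection, which zeroes out every rule whose
left-hand side differs from the top of the derivation stack, so any decoded
sequence is grammatically consistent by construction (chemical validity is
a separate question).

The shipped default grammar (``data/smiles_cfg.txt``) is the grammar-VAE
style SMILES CFG covering organic-subset atoms, bracket atoms, rings and
branches; it is stored as data so dialects can be swapped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from gexmol.exceptions import ConfigurationError, DerivationError, SmilesParseError

__all__ = [
    "GrammarSpec",
    "RuleSequence",
    "build_grammar",
    "smiles_to_rules",
    "rules_to_smiles",
    "one_hot_encode",
    "one_hot_decode",
    "masked_decode",
]


@dataclass(frozen=True)
class Production:
    lhs: str
    rhs: tuple[str, ...]  # empty tuple = epsilon (the padding rule)

    def __str__(self):
        return f"{self.lhs} -> {' '.join(self.rhs) if self.rhs else 'None'}"


@dataclass
class GrammarSpec:
    """An ordered production-rule set over SMILES tokens."""

    rules: list[Production]
    start_symbol: str
    padding_rule_index: int
    lhs_index: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.lhs_index:
            self.lhs_index = {}
            for i, rule in enumerate(self.rules):
                self.lhs_index.setdefault(rule.lhs, []).append(i)
        self.nonterminals = set(self.lhs_index)
        self.terminals = sorted(
            {s for r in self.rules for s in r.rhs if s not in self.nonterminals},
            key=len,
            reverse=True,
        )
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.start_symbol not in self.lhs_index:
            raise ConfigurationError(f"start symbol {self.start_symbol!r} has no production")
        pad = self.rules[self.padding_rule_index]
        if pad.rhs != ():
            raise ConfigurationError("padding rule must have an empty right-hand side")
        epsilons = [i for i, r in enumerate(self.rules) if r.rhs == ()]
        if epsilons != [self.padding_rule_index]:
            raise ConfigurationError("exactly one epsilon (padding) rule is allowed")
        for rule in self.rules:
            for sym in rule.rhs:
                if sym in self.nonterminals and sym not in self.lhs_index:
                    raise ConfigurationError(f"nonterminal {sym!r} has no production")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def is_terminal(self, symbol: str) -> bool:
        return symbol not in self.nonterminals

    # -- serialization --------------------------------------------------------
    def to_text(self) -> str:
        lines = []
        for rule in self.rules:
            rhs = " ".join(
                f"'{s}'" if self.is_terminal(s) else s for s in rule.rhs
            ) or "None"
            lines.append(f"{rule.lhs} -> {rhs}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GrammarSpec":
        rules: list[Production] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            lhs, _, rhs_text = line.partition("->")
            lhs = lhs.strip()
            rhs_text = rhs_text.strip()
            if not lhs or not rhs_text:
                raise ConfigurationError(f"malformed production: {raw!r}")
            if rhs_text == "None":
                rhs: tuple[str, ...] = ()
            else:
                rhs = tuple(
                    tok[1:-1] if tok.startswith("'") and tok.endswith("'") else tok
                    for tok in rhs_text.split()
                )
            rules.append(Production(lhs, rhs))
        pad = [i for i, r in enumerate(rules) if r.rhs == ()]
        if len(pad) != 1:
            raise ConfigurationError("grammar must define exactly one padding rule")
        return cls(rules=rules, start_symbol=rules[0].lhs, padding_rule_index=pad[0])


_VARIANTS = {"smiles": "smiles_cfg.txt", "smiles_cfg": "smiles_cfg.txt"}


@lru_cache(maxsize=None)
def build_grammar(variant: str = "smiles") -> GrammarSpec:
    """Load a shipped grammar dialect; deterministic rule ordering."""
    try:
        fname = _VARIANTS[variant]
    except KeyError:
        raise ConfigurationError(
            f"unknown grammar variant {variant!r}; available: {sorted(set(_VARIANTS))}"
        ) from None
    text = resources.files("gexmol.data").joinpath(fname).read_text()
    return GrammarSpec.from_text(text)


# ---------------------------------------------------------------------------
# rule sequences


@dataclass
class RuleSequence:
    """A molecule as a padded leftmost-derivation rule-index sequence."""

    indices: np.ndarray  # shape (T,), int
    grammar_n_rules: int
    truncated: bool = False

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)

    @property
    def max_len(self) -> int:
        return int(self.indices.shape[0])

    def __len__(self):
        return self.max_len

    def __eq__(self, other):
        return (
            isinstance(other, RuleSequence)
            and np.array_equal(self.indices, other.indices)
            and self.truncated == other.truncated
        )


def derivation_length(seq: RuleSequence, grammar: GrammarSpec) -> int:
    """Number of non-padding steps before the padding tail."""
    nonpad = np.nonzero(seq.indices != grammar.padding_rule_index)[0]
    return 0 if nonpad.size == 0 else int(nonpad[-1]) + 1


def is_derivation_consistent(seq: RuleSequence, grammar: GrammarSpec) -> bool:
    try:
        _replay(seq, grammar)
    except DerivationError:
        return seq.truncated and _replay_ok_until_truncation(seq, grammar)
    return True


def _replay_ok_until_truncation(seq: RuleSequence, grammar: GrammarSpec) -> bool:
    try:
        _replay(seq, grammar, allow_unfinished=True)
        return True
    except DerivationError:
        return False


# ---------------------------------------------------------------------------
# tokenizer + span parser


def tokenize(smiles: str, grammar: GrammarSpec) -> list[str]:
    """Greedy longest-match tokenization over the grammar's terminal set."""
    tokens = []
    i = 0
    while i < len(smiles):
        for term in grammar.terminals:  # sorted longest-first
            if smiles.startswith(term, i):
                tokens.append(term)
                i += len(term)
                break
        else:
            raise SmilesParseError(
                f"unknown token at position {i}: {smiles[i:]!r}", position=i
            )
    return tokens


def _parse_tree(tokens: list[str], grammar: GrammarSpec):
    """Memoized span parser returning a parse tree (rule_idx, children).

    The grammar has no reachable epsilon productions, so every symbol spans
    at least one token and recursion terminates despite left recursion.
    """
    n = len(tokens)
    memo: dict = {}

    def parse_nt(sym: str, i: int, j: int):
        key = (sym, i, j)
        if key in memo:
            return memo[key]
        memo[key] = None  # guards left-recursive re-entry on the same span
        result = None
        for ridx in grammar.lhs_index[sym]:
            rhs = grammar.rules[ridx].rhs
            if not rhs or len(rhs) > j - i:
                continue
            children = match_seq(rhs, i, j)
            if children is not None:
                result = (ridx, children)
                break
        memo[key] = result
        return result

    seq_memo: dict = {}

    def match_seq(syms: tuple[str, ...], i: int, j: int):
        key = (syms, i, j)
        if key in seq_memo:
            return seq_memo[key]
        if not syms:
            out = [] if i == j else None
            seq_memo[key] = out
            return out
        head, rest = syms[0], syms[1:]
        out = None
        if grammar.is_terminal(head):
            if i < j and tokens[i] == head:
                tail = match_seq(rest, i + 1, j)
                if tail is not None:
                    out = [head] + tail
        else:
            lo = i + 1
            hi = j - len(rest)
            for k in range(lo, hi + 1):
                sub = parse_nt(head, i, k)
                if sub is None:
                    continue
                tail = match_seq(rest, k, j)
                if tail is not None:
                    out = [sub] + tail
                    break
        seq_memo[key] = out
        return out

    return parse_nt(grammar.start_symbol, 0, n)


def smiles_to_rules(smiles: str, grammar: GrammarSpec, max_len: int) -> RuleSequence:
    """Parse a SMILES into its padded leftmost-derivation rule sequence."""
    tokens = tokenize(smiles, grammar)
    if not tokens:
        raise SmilesParseError("empty SMILES string", position=0)
    tree = _parse_tree(tokens, grammar)
    if tree is None:
        raise SmilesParseError(
            f"SMILES {smiles!r} does not parse under the grammar", position=0
        )
    indices: list[int] = []

    stack = [tree]
    while stack:
        node = stack.pop()
        if isinstance(node, str):
            continue
        ridx, children = node
        indices.append(ridx)
        stack.extend(reversed(children))

    if len(indices) > max_len:
        raise SmilesParseError(
            f"derivation length {len(indices)} exceeds max_len={max_len}"
        )
    padded = np.full(max_len, grammar.padding_rule_index, dtype=np.int64)
    padded[: len(indices)] = indices
    return RuleSequence(padded, grammar.n_rules)


def _replay(seq: RuleSequence, grammar: GrammarSpec, allow_unfinished: bool = False) -> str:
    """Replay a derivation with a symbol stack, returning the terminal string."""
    out: list[str] = []
    stack: list[str] = [grammar.start_symbol]
    indices = seq.indices
    t = 0
    T = len(indices)
    while stack:
        while stack and grammar.is_terminal(stack[-1]):
            out.append(stack.pop())
        if not stack:
            break
        if t >= T:
            if allow_unfinished:
                return "".join(out)
            raise DerivationError(
                f"derivation unfinished after {T} steps (stack depth {len(stack)})"
            )
        ridx = int(indices[t])
        rule = grammar.rules[ridx]
        if ridx == grammar.padding_rule_index:
            raise DerivationError(
                f"step {t}: padding rule applied while stack top is {stack[-1]!r}"
            )
        if rule.lhs != stack[-1]:
            raise DerivationError(
                f"step {t}: rule {rule} does not match stack top {stack[-1]!r}"
            )
        stack.pop()
        stack.extend(reversed(rule.rhs))
        t += 1
    # all remaining entries must be padding
    if np.any(indices[t:] != grammar.padding_rule_index):
        bad = t + int(np.nonzero(indices[t:] != grammar.padding_rule_index)[0][0])
        raise DerivationError(f"step {bad}: non-padding rule after derivation finished")
    if t == 0:
        raise DerivationError("empty derivation (padding-only sequence)")
    return "".join(out)


def rules_to_smiles(seq: RuleSequence, grammar: GrammarSpec) -> str:
    """Expand a derivation-consistent rule sequence back to its SMILES string."""
    if seq.truncated:
        raise DerivationError("sequence was truncated; cannot expand to SMILES")
    return _replay(seq, grammar)


# ---------------------------------------------------------------------------
# one-hot form


def one_hot_encode(seq: RuleSequence, grammar: GrammarSpec) -> np.ndarray:
    """T × R binary matrix; row t is the one-hot of ``seq.indices[t]``."""
    T = seq.max_len
    mat = np.zeros((T, grammar.n_rules), dtype=np.float64)
    mat[np.arange(T), seq.indices] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray, grammar: GrammarSpec) -> RuleSequence:
    return RuleSequence(np.argmax(matrix, axis=1), grammar.n_rules)


# ---------------------------------------------------------------------------
# stack-masked decoding


def lhs_masks(grammar: GrammarSpec) -> dict[str, np.ndarray]:
    """Boolean mask per nonterminal selecting the rules it can expand by."""
    masks = {}
    for nt, idxs in grammar.lhs_index.items():
        m = np.zeros(grammar.n_rules, dtype=bool)
        m[idxs] = True
        masks[nt] = m
    return masks


def masked_decode(
    logits: np.ndarray,
    grammar: GrammarSpec,
    mode: str = "argmax",
    seed: int | None = None,
) -> RuleSequence:
    """Select one rule per step, masked to the derivation stack's top symbol.

    Rules whose left-hand side differs from the stack top get probability
    zero, so the output is always derivation-consistent.  If the stack is
    not empty after T steps the result carries ``truncated=True``.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    T, R = logits.shape
    if R != grammar.n_rules:
        raise ValueError(f"logit width {R} != rule count {grammar.n_rules}")
    if mode not in ("argmax", "sample"):
        raise ConfigurationError(f"unknown decode mode {mode!r}")
    rng = np.random.default_rng(seed)
    masks = lhs_masks(grammar)

    indices = np.full(T, grammar.padding_rule_index, dtype=np.int64)
    stack: list[str] = [grammar.start_symbol]
    truncated = False
    for t in range(T):
        while stack and grammar.is_terminal(stack[-1]):
            stack.pop()
        if not stack:
            break
        mask = masks[stack[-1]]
        row = np.where(mask, logits[t], -np.inf)
        if mode == "argmax":
            choice = int(np.argmax(row))
        else:
            p = np.exp(row - row.max())
            p /= p.sum()
            choice = int(rng.choice(R, p=p))
        indices[t] = choice
        stack.pop()
        stack.extend(reversed(grammar.rules[choice].rhs))
    else:
        while stack and grammar.is_terminal(stack[-1]):
            stack.pop()
        truncated = bool(stack)
    return RuleSequence(indices, grammar.n_rules, truncated=truncated)
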