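"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the definitions, separately
from the package code paths it checks: a quadratic Jaro matcher, a naive
Boolean-query evaluator, and a random AST generator for fuzzing.
"""

from __future__ import annotations

import random
import string


# ---------------------------------------------------------------------------
# brute-force Jaro / Jaro–Winkler
# ---------------------------------------------------------------------------


def ref_jaro(s1: str, s2: str) -> float:
    """Quadratic-scan Jaro similarity straight from the definition."""
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(len(s1), len(s2)) // 2 - 1
    if window < 0:
        window = 0
    # assign each character of s1, left to right, to the leftmost unused
    # equal character of s2 within the window (scanning all of s2 and
    # filtering on |i - j|, rather than slicing a window)
    seq1: list[str] = []  # matched characters of s1, in s1 order
    used: set[int] = set()
    for i, c in enumerate(s1):
        for j in range(len(s2)):
            if j in used or abs(i - j) > window:
                continue
            if s2[j] == c:
                seq1.append(c)
                used.add(j)
                break
    m = len(seq1)
    if m == 0:
        return 0.0
    seq2 = [s2[j] for j in sorted(used)]  # matched characters of s2, in s2 order
    t = sum(1 for a, b in zip(seq1, seq2) if a != b) / 2.0
    return (m / len(s1) + m / len(s2) + (m - t) / m) / 3.0


def ref_jaro_winkler(s1: str, s2: str, p: float = 0.1, l_max: int = 4) -> float:
    base = ref_jaro(s1, s2)
    l = 0
    while l < min(len(s1), len(s2), l_max) and s1[l] == s2[l]:
        l += 1
    return base + l * p * (1.0 - base)


def random_string_pairs(n: int, seed: int) -> list[tuple[str, str]]:
    rng = random.Random(seed)
    alphabet = string.ascii_uppercase[:8]
    pairs = []
    for _ in range(n):
        a = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 12)))
        if rng.random() < 0.5:
            # perturbed copy: realistic near-duplicates
            b = list(a)
            for _ in range(rng.randint(0, 3)):
                if not b:
                    break
                op = rng.choice(("del", "swap", "sub"))
                i = rng.randrange(len(b))
                if op == "del":
                    del b[i]
                elif op == "sub":
                    b[i] = rng.choice(alphabet)
                elif len(b) > 1:
                    j = rng.randrange(len(b))
                    b[i], b[j] = b[j], b[i]
            b = "".join(b)
        else:
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 12)))
        pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# naive Boolean query evaluation (no regex, no shared helpers)
# ---------------------------------------------------------------------------


def _naive_occurs(needle: str, text: str) -> bool:
    """Scan for a whole-token occurrence by explicit boundary inspection."""
    tl = " ".join(text.casefold().split())
    nd = " ".join(needle.casefold().split())
    start = 0
    while True:
        i = tl.find(nd, start)
        if i == -1:
            return False
        before_ok = i == 0 or not (tl[i - 1].isalnum() or tl[i - 1] == "_")
        after = i + len(nd)
        after_ok = after == len(tl) or not (tl[after].isalnum() or tl[after] == "_")
        if before_ok and after_ok:
            return True
        start = i + 1


def ref_evaluate(ast, text: str, lemma_variants=None) -> bool:
    """Fold Boolean operators over naively computed leaf matches."""
    from litcurate.query import And, Not, Or, Phrase, Term

    if isinstance(ast, Term):
        variants = lemma_variants(ast.text) if lemma_variants else {ast.text}
        return any(_naive_occurs(v, text) for v in variants)
    if isinstance(ast, Phrase):
        return _naive_occurs(ast.text, text)
    if isinstance(ast, Not):
        return not ref_evaluate(ast.child, text, lemma_variants)
    if isinstance(ast, And):
        return all(ref_evaluate(c, text, lemma_variants) for c in ast.children)
    if isinstance(ast, Or):
        return any(ref_evaluate(c, text, lemma_variants) for c in ast.children)
    raise TypeError(ast)


# ---------------------------------------------------------------------------
# random AST / document generation
# ---------------------------------------------------------------------------

_WORDS = [
    "neuron", "dendrite", "axon", "soma", "spine", "branch", "tracing",
    "morphology", "cortex", "mouse", "rat", "human", "synapse", "glia",
]


def random_ast(rng: random.Random, depth: int = 0):
    from litcurate.query import And, Not, Or, Phrase, Term

    r = rng.random()
    if depth >= 3 or r < 0.45:
        if rng.random() < 0.3:
            return Phrase(" ".join(rng.sample(_WORDS, rng.randint(2, 3))))
        return Term(rng.choice(_WORDS))
    if r < 0.6:
        return Not(random_ast(rng, depth + 1))
    # canonical form: same-operator children are flattened, as the parser
    # produces for associative chains
    op = And if r < 0.8 else Or
    kids: list = []
    for _ in range(rng.randint(2, 3)):
        child = random_ast(rng, depth + 1)
        if isinstance(child, op):
            kids.extend(child.children)
        else:
            kids.append(child)
    return op(tuple(kids))


def random_document(rng: random.Random) -> str:
    n = rng.randint(5, 25)
    return " ".join(rng.choice(_WORDS) for _ in range(n)) + "."
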