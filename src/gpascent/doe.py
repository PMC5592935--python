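"""Two-level factorial design of experiments on coded variables.

Factors are linearly rescaled so that the low level maps to -1 and the high
level to +1 ("coded units"); a full 2^p factorial enumerates every sign
vector, and a regular half fraction keeps the runs whose product over the
letters of the defining relation (e.g. I = -ABCDE) equals the relation's
sign.  Effects in a fraction are aliased by word multiplication modulo
squared letters.  First-order response models are fit by ordinary least
squares on the coded main effects; on an orthogonal +-1 design each slope
equals half the difference between the mean response at the high and low
levels, which serves as an independent cross-check.  The Box-Cox power
transform of a positive response is included for response-metric
exploration.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigurationError

__all__ = [
    "Factor",
    "CodedDesign",
    "FirstOrderFit",
    "code_value",
    "decode_value",
    "full_factorial",
    "half_fraction",
    "alias_structure",
    "fit_first_order",
    "box_cox",
    "box_cox_mle",
]

LETTERS = "ABCDEFGHIJKLMNOPQRST"


@dataclass(frozen=True)
class Factor:
    """One design variable with its two-level region and operability bounds."""

    name: str
    low: float
    high: float
    integer_valued: bool = False
    operability_min: float = -math.inf
    operability_max: float = math.inf

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(f"{self.name}: low must be < high")
        if self.low < self.operability_min or self.high > self.operability_max:
            raise ConfigurationError(f"{self.name}: [low, high] outside the operability region")

    @property
    def base(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return self.base - self.low

    def clamp(self, z: float) -> float:
        return min(max(z, self.operability_min), self.operability_max)

    def round_natural(self, z: float) -> float:
        """Presentation rounding: integers for counts, 2 decimals otherwise."""
        return float(round(z)) if self.integer_valued else round(z, 2)


def code_value(factor: Factor, z: float) -> float:
    """Natural units -> coded units (low -> -1, high -> +1, linear beyond)."""
    if factor.half_range == 0:
        raise ConfigurationError(f"{factor.name}: degenerate factor (zero half-range)")
    return (z - factor.base) / factor.half_range


def decode_value(factor: Factor, x: float) -> float:
    """Coded units -> natural units; exact inverse of :func:`code_value`."""
    return factor.base + x * factor.half_range


@dataclass
class CodedDesign:
    """A set of two-level runs in coded units.

    ``runs`` is a (runs x p) matrix of -1/+1; ``names`` labels the columns;
    ``defining_relation`` (e.g. ``"I=-ABCDE"``) is set for regular fractions.
    """

    names: list[str]
    runs: np.ndarray
    defining_relation: str | None = None
    factors: list[Factor] | None = None

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=int)
        if not np.isin(self.runs, (-1, 1)).all():
            raise ConfigurationError("coded runs must contain only -1 and +1")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs, columns=self.names)
        if self.factors is not None:
            for f, name in zip(self.factors, self.names):
                df[f"{name}_natural"] = [f.round_natural(decode_value(f, x)) for x in df[name]]
        return df


def full_factorial(p: int, names: list[str] | None = None) -> CodedDesign:
    """All 2^p sign vectors in lexicographic order (-1 before +1)."""
    if not 1 <= p <= 20:
        raise ConfigurationError("p must be between 1 and 20")
    runs = np.array(list(itertools.product((-1, 1), repeat=p)), dtype=int)
    return CodedDesign(names or list(LETTERS[:p]), runs)


def _parse_word(word: str, names: list[str]) -> tuple[int, list[int]]:
    """Parse a generator word like ``"-ABCDE"`` into (sign, column indices)."""
    word = word.strip().upper()
    m = re.fullmatch(r"(I\s*=\s*)?([+-]?)([A-Z]+)", word)
    if not m:
        raise ConfigurationError(f"malformed generator word {word!r}")
    sign = -1 if m.group(2) == "-" else 1
    letters = list(m.group(3))
    if len(set(letters)) != len(letters):
        raise ConfigurationError(f"generator word {word!r} repeats a letter")
    try:
        cols = [names.index(c) for c in letters]
    except ValueError as exc:
        raise ConfigurationError(f"generator letter outside the design: {exc}") from None
    return sign, cols


def half_fraction(
    p: int,
    generator_word: str | None = None,
    sign: int = 1,
    names: list[str] | None = None,
) -> CodedDesign:
    """The 2^(p-1) runs whose generator-column product equals ``sign``.

    ``generator_word`` defaults to the full word over all p letters (the
    resolution-maximal choice); a leading ``+``/``-`` inside the word
    overrides ``sign``.
    """
    names = names or list(LETTERS[:p])
    word = generator_word or "".join(names)
    wsign, cols = _parse_word(word, names)
    if any(c in "+-" for c in word):
        sign = wsign
    if sign not in (-1, 1):
        raise ConfigurationError("sign must be +1 or -1")
    full = full_factorial(p, names)
    keep = full.runs[:, cols].prod(axis=1) == sign
    letters = "".join(names[c] for c in sorted(cols))
    rel = f"I={'+' if sign > 0 else '-'}{letters}"
    return CodedDesign(names, full.runs[keep], defining_relation=rel)


def _word_multiply(w1: str, w2: str) -> str:
    """Multiply effect words, cancelling squared letters (A*ABC = BC)."""
    out = set(w1) ^ set(w2)
    return "".join(sorted(out)) or "I"


def alias_structure(design: CodedDesign) -> dict[str, str]:
    """Map every factorial effect of the fraction to its alias.

    Each effect word is multiplied by the defining word with squared letters
    cancelled; the identity maps to the full defining word.
    """
    if design.defining_relation is None:
        raise ConfigurationError("design has no defining relation")
    _, cols = _parse_word(design.defining_relation, design.names)
    word = "".join(design.names[c] for c in sorted(cols))
    aliases = {"I": word}
    for k in range(1, len(design.names) + 1):
        for combo in itertools.combinations(design.names, k):
            effect = "".join(combo)
            if effect != word:
                aliases[effect] = _word_multiply(effect, word)
    return aliases


@dataclass
class FirstOrderFit:
    """OLS fit of a main-effects model on coded variables."""

    intercept: float
    slopes: dict[str, float]
    residual_variance: float
    response_name: str = "y"

    def slope_vector(self, names: list[str] | None = None) -> np.ndarray:
        names = names or list(self.slopes)
        return np.array([self.slopes[n] for n in names])


def fit_first_order(
    design: CodedDesign, responses: np.ndarray, response_name: str = "y"
) -> FirstOrderFit:
    """Ordinary least squares of the responses on intercept + coded main effects."""
    y = np.asarray(responses, dtype=float)
    if y.shape != (design.n_runs,):
        raise ConfigurationError("need exactly one response per run")
    p = len(design.names)
    if design.n_runs < p + 1:
        raise ConfigurationError("need at least p+1 runs to fit p slopes")
    X = np.column_stack([np.ones(design.n_runs), design.runs])
    rank = np.linalg.matrix_rank(X)
    if rank < p + 1:
        corr = np.corrcoef(design.runs, rowvar=False)
        bad = [
            f"{design.names[i]}~{design.names[j]}"
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ConfigurationError(f"singular design; collinear columns: {', '.join(bad) or 'unknown'}")
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    dof = design.n_runs - (p + 1)
    s2 = float(resid @ resid / dof) if dof > 0 else float("nan")
    return FirstOrderFit(float(b[0]), dict(zip(design.names, map(float, b[1:]))), s2, response_name)


def box_cox(y: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox power transform (y^lam - 1)/lam, log for lam = 0; y must be > 0."""
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ConfigurationError("Box-Cox requires strictly positive responses")
    return special.boxcox(y, lam)


def box_cox_mle(y: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Profile-likelihood estimate of the Box-Cox power over a lambda grid."""
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ConfigurationError("Box-Cox requires strictly positive responses")
    grid = np.linspace(-2.0, 2.0, 81) if grid is None else np.asarray(grid, dtype=float)
    ll = np.array([stats.boxcox_llf(l, y) for l in grid])
    return float(grid[np.argmax(ll)])
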