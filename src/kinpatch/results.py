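"""Shared result containers for Monte Carlo / permutation tests and regressions."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TestResult:
    """Outcome of a randomization test.

    ``statistic`` semantics depend on the test (conditional table
    probability, homozygote count, Mantel r, graph transitivity ...).
    Monte Carlo p-values use the add-one rule (x + 1) / (n + 1), so p is
    never exactly 0 and lies in (0, 1].
    """

    statistic: float
    p_value: float
    n_mc: int
    tail: str  # "lower" | "upper" | "two-sided"
    seed: int | None = None
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0, "add-one rule keeps p in (0, 1]"
        assert self.tail in ("lower", "upper", "two-sided")


@dataclass
class RegressionResult:
    """Ordinary least-squares fit summary (y on a single predictor)."""

    slope: float
    intercept: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    n: int

    def __post_init__(self) -> None:
        assert self.df_den == self.n - 2
        assert self.f_statistic >= 0.0
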