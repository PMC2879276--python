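"""Random-retroposition null model and heterogeneity test.

The null model follows the classical expectation for inter-chromosomal
retroposition: a retrogene's source element is drawn proportionally to the
element's (dosage-weighted) gene count, and its target proportionally to the
euchromatic size of each *other* element.  Ordered element pairs are then
pooled into movement classes (X->A, A->X, A->A, and X->X where a karyotype
has two X-linked elements), and observed class counts are compared to the
expectation with a Pearson chi-square test; a multinomial Monte-Carlo
version guards against small expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import yaml
from scipy import stats

from .types import ChiSquareResult, RetromoveError


@dataclass(frozen=True)
class NullModelConfig:
    """Per-element gene counts ``g_i`` (genes), euchromatin sizes ``s_i``
    (Mb), dosage source weights ``w_i`` (dimensionless, 1 for autosomes) and
    the set of X-linked elements defining the class partition."""

    gene_counts: Mapping[str, float]
    sizes_mb: Mapping[str, float]
    weights: Mapping[str, float]
    x_linked: frozenset[str]
    exclude_same_element: bool = True
    calibrated: bool = False

    def __post_init__(self) -> None:
        for e in self.gene_counts:
            if self.gene_counts[e] <= 0 or self.sizes_mb[e] <= 0:
                raise ValueError(f"element {e}: g and s must be positive")
            if self.weights.get(e, 1.0) <= 0:
                raise ValueError(f"element {e}: weight must be positive")

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted(self.gene_counts))

    def pair_class(self, source: str, target: str) -> str:
        src = "X" if source in self.x_linked else "A"
        tgt = "X" if target in self.x_linked else "A"
        return f"{src}->{tgt}"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "NullModelConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        els = doc["elements"]
        return cls(
            gene_counts={e: float(v["gene_count"]) for e, v in els.items()},
            sizes_mb={e: float(v["size_mb"]) for e, v in els.items()},
            weights={e: float(v.get("weight", 1.0)) for e, v in els.items()},
            x_linked=frozenset(doc.get("x_linked", ["A"])),
            exclude_same_element=bool(doc.get("exclude_same_element", True)),
            calibrated=bool(doc.get("calibrated", False)),
        )


def load_default_null_config() -> NullModelConfig:
    """The packaged D. melanogaster configuration (calibrated X weight)."""
    from .data_io import default_null_config_path

    return NullModelConfig.from_yaml(default_null_config_path())


def class_probabilities(cfg: NullModelConfig) -> dict[str, float]:
    """Movement-class probabilities under the null.

    P(source=i) = w_i g_i / sum_k w_k g_k and, given the source,
    P(target=j | i) = s_j / sum_{k != i} s_k; class probability is the sum
    over the ordered inter-element pairs the class contains.  Classes with
    no pairs under the configured karyotype are omitted.
    """
    els = cfg.elements
    wg = {e: cfg.weights.get(e, 1.0) * cfg.gene_counts[e] for e in els}
    z = sum(wg.values())
    total_s = sum(cfg.sizes_mb[e] for e in els)
    if z <= 0:
        raise RetromoveError("zero source normalizer")
    probs: dict[str, float] = {}
    for i in els:
        denom = total_s - (cfg.sizes_mb[i] if cfg.exclude_same_element else 0.0)
        if denom <= 0:
            raise RetromoveError("zero target normalizer")
        for j in els:
            if cfg.exclude_same_element and i == j:
                continue
            p = (wg[i] / z) * (cfg.sizes_mb[j] / denom)
            cls = cfg.pair_class(i, j)
            probs[cls] = probs.get(cls, 0.0) + p
    return probs


def expected_counts(cfg: NullModelConfig, n_events: int) -> dict[str, float]:
    """Expected movement counts per class for ``n_events`` total events."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return {c: n_events * p for c, p in class_probabilities(cfg).items()}


def chi_square_test(
    observed: Mapping[str, float], expected: Mapping[str, float]
) -> ChiSquareResult:
    """Pearson chi-square heterogeneity test of observed vs expected counts,
    with df = number of classes - 1."""
    if set(observed) != set(expected):
        raise RetromoveError(
            f"category mismatch: {sorted(observed)} vs {sorted(expected)}"
        )
    cats = tuple(sorted(observed))
    obs = np.array([float(observed[c]) for c in cats])
    exp = np.array([float(expected[c]) for c in cats])
    if np.any(exp <= 0):
        raise RetromoveError("expected count must be positive in every class")
    # scipy.stats.chisquare requires sum(O) == sum(E); compute directly so
    # externally supplied expectations need not be renormalized
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = len(cats) - 1
    pvalue = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(
        observed=tuple(obs), expected=tuple(exp), categories=cats,
        statistic=statistic, df=df, pvalue=pvalue,
    )


def multinomial_mc_test(
    observed: Mapping[str, float],
    cfg: NullModelConfig,
    reps: int = 100_000,
    seed: int = 0,
) -> ChiSquareResult:
    """Monte-Carlo multinomial version of the heterogeneity test.

    Replicate counts are drawn from the null class probabilities at the
    observed total; p = (1 + #{chi2_rep >= chi2_obs}) / (reps + 1).
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    probs = class_probabilities(cfg)
    exp = expected_counts(cfg, int(round(sum(observed.values()))))
    base = chi_square_test(observed, exp)
    cats = base.categories
    p = np.array([probs[c] for c in cats])
    p = p / p.sum()
    n = int(round(sum(observed.values())))
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, p, size=reps)
    e = np.asarray(base.expected)
    chi2_reps = np.sum((draws - e) ** 2 / e, axis=1)
    mc_p = (1 + int(np.sum(chi2_reps >= base.statistic - 1e-12))) / (reps + 1)
    return ChiSquareResult(
        observed=base.observed, expected=base.expected, categories=cats,
        statistic=base.statistic, df=base.df, pvalue=base.pvalue,
        mc_pvalue=float(mc_p), mc_reps=reps, mc_seed=seed,
    )


def calibrate_x_weight(
    gene_counts: Mapping[str, float],
    sizes_mb: Mapping[str, float],
    observed: Mapping[str, float],
    target_statistic: float,
    x_linked: Iterable[str] = ("A",),
    bracket: tuple[float, float] = (1.0, 2.0),
) -> float:
    """Solve the X dosage weight so the chi-square statistic of ``observed``
    against the model expectation equals ``target_statistic``."""
    from scipy.optimize import brentq

    xs = frozenset(x_linked)
    n = int(round(sum(observed.values())))

    def stat(w: float) -> float:
        cfg = NullModelConfig(
            gene_counts=gene_counts, sizes_mb=sizes_mb,
            weights={e: (w if e in xs else 1.0) for e in gene_counts},
            x_linked=xs,
        )
        return chi_square_test(observed, expected_counts(cfg, n)).statistic

    return float(
        brentq(lambda w: stat(w) - target_statistic, *bracket, xtol=1e-12)
    )
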