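"""Pooled-bootstrap null test for treatment differences in replicate means.

The test pools the treatment and control replicate means (six each in the
full design), draws two independent sets of B bootstrap means (each the
mean of m draws with replacement from the pool), and differences the sets
elementwise to form a null distribution of mean differences under "no
treatment effect".  The observed nestbox-minus-control difference is then
referred to that null distribution with an add-one empirical P-value,
(1 + #exceedances) / (B + 1), so P is never zero and has resolution
1/(B+1); at the default B = 1000 the smallest attainable P is just under
0.001.
"""

from __future__ import annotations

import dataclasses
import zlib
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapResult",
    "pooled_bootstrap_null",
    "empirical_p",
    "run_bootstrap_suite",
    "response_seed",
]

SIDEDNESS = ("two_sided", "one_sided_greater")


@dataclasses.dataclass(frozen=True)
class BootstrapResult:
    response: str
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    B: int
    m: int
    seed: int
    sidedness: str


def pooled_bootstrap_null(trt: Sequence[float], ctrl: Sequence[float],
                          B: int = 1000, m: int = 6,
                          seed: int | np.random.SeedSequence | None = None,
                          ) -> np.ndarray:
    """Null distribution of mean differences from the pooled replicate means.

    Draws 2B bootstrap means of size ``m`` (with replacement) from the
    pooled values and returns the elementwise difference of the first and
    second set, in generation order.
    """
    trt = np.asarray(trt, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if trt.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    # sorting makes the realized draw invariant to group labelling and
    # replicate order without changing the bootstrap law
    pool = np.sort(np.concatenate([trt, ctrl]))
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(2, B, m), replace=True)
    means = draws.mean(axis=2)
    return means[0] - means[1]


def empirical_p(observed: float, null_diffs: np.ndarray,
                sidedness: str = "two_sided") -> float:
    """Add-one empirical P of ``observed`` against a null sample.

    Ties count as exceedances, so an observed difference of zero always
    yields P = 1 under the two-sided rule.
    """
    null_diffs = np.asarray(null_diffs, dtype=float)
    if null_diffs.size == 0:
        raise ValueError("null_diffs must be non-empty")
    if sidedness == "two_sided":
        r = int(np.sum(np.abs(null_diffs) >= abs(observed)))
    elif sidedness == "one_sided_greater":
        r = int(np.sum(null_diffs >= observed))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}; expected one of {SIDEDNESS}")
    return (1 + r) / (null_diffs.size + 1)


def response_seed(master_seed: int, response: str) -> np.random.SeedSequence:
    """Independent substream per response keyed by name, so adding or
    reordering responses never perturbs another response's draw."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(response.encode())])


def run_bootstrap_suite(replicates: pd.DataFrame,
                        responses: Sequence[str] | None = None,
                        B: int = 1000, m: int = 6, seed: int = 0,
                        sidedness: str = "two_sided") -> list[BootstrapResult]:
    """Bootstrap test of nestbox vs control for each response.

    ``replicates`` is the tidy output of
    :func:`vinebirds.summaries.replicate_means`.  Each response must have a
    complete design (no missing cells); otherwise the missing cells are
    reported in the error.
    """
    if responses is None:
        responses = list(dict.fromkeys(replicates["response"]))
    results = []
    for name in responses:
        sub = replicates[replicates["response"] == name]
        if sub.empty:
            raise ValueError(f"response {name!r} absent from replicate table")
        missing = sub[sub["value"].isna()]
        if not missing.empty:
            cells = [tuple(t) for t in missing[["area", "site", "period"]].itertuples(index=False)]
            raise ValueError(f"response {name!r}: incomplete design, missing cells {cells}")
        trt = sub.loc[sub["area"] == "nestbox", "value"].to_numpy()
        ctrl = sub.loc[sub["area"] == "control", "value"].to_numpy()
        ss = response_seed(seed, name)
        null = pooled_bootstrap_null(trt, ctrl, B=B, m=m, seed=ss)
        observed = float(trt.mean() - ctrl.mean())
        p = empirical_p(observed, null, sidedness)
        results.append(
            BootstrapResult(response=name, observed_diff=observed, null_diffs=null,
                            p_value=p, B=B, m=m, seed=seed, sidedness=sidedness)
        )
    return results


def results_to_frame(results: Sequence[BootstrapResult]) -> pd.DataFrame:
    """One-row-per-response summary table of bootstrap results."""
    return pd.DataFrame(
        [
            {
                "response": r.response,
                "observed_diff": r.observed_diff,
                "p_value": r.p_value,
                "B": r.B,
                "m": r.m,
                "sidedness": r.sidedness,
            }
            for r in results
        ]
    )
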