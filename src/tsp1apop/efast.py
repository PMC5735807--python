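"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis via sinusoidal search curves:
each input is assigned a driving frequency and explored along
x(s) = 0.5 + (1/pi) * arcsin(sin(w*s + phi)); the first-order index S_i is
the fraction of output variance at the driving frequency and its first M
harmonics, and the total-order index S_T is one minus the variance at the
complementary (low) frequencies.  A dummy input that the model never reads
is carried through the analysis as the significance reference.

Inputs are varied one order of magnitude above and below their baseline
value; the spacing across that range is log-uniform by default because the
range is multiplicative (a ``linear`` mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EfastDesign",
    "EfastSample",
    "SensitivityResult",
    "efast_sample",
    "efast_indices",
    "rank_influential",
]

DUMMY_NAME = "_dummy"


@dataclass(frozen=True)
class EfastDesign:
    """Sampling design for eFAST.

    ``bounds`` maps each input to its (low, high) range; the conventional
    choice for this model is (0.1x, 10x) the baseline.  ``n_samples`` is
    the number of points per search curve (65 is the standard minimum;
    513 is the default), ``n_resamples`` the number of random phase
    shifts, and ``interference`` the harmonic order M.
    """

    inputs: tuple
    bounds: dict
    n_samples: int = 513
    n_resamples: int = 5
    interference: int = 4
    spacing: str = "log"  # or "linear"
    include_dummy: bool = True

    def __post_init__(self):
        if self.n_samples < 65:
            raise ValueError("need >= 65 samples per curve")
        if self.spacing not in ("log", "linear"):
            raise ValueError("spacing must be 'log' or 'linear'")
        for name in self.inputs:
            lo, hi = self.bounds[name]
            if not (0 <= lo < hi):
                raise ValueError(f"bad range for {name!r}")
            if self.spacing == "log" and lo <= 0:
                raise ValueError(f"log spacing needs positive bounds ({name!r})")

    @property
    def all_inputs(self) -> tuple:
        return self.inputs + ((DUMMY_NAME,) if self.include_dummy else ())

    def frequencies(self) -> tuple:
        """(driving frequency, max complementary frequency).

        The driving frequency is (Ns-1)/(2M); complementary frequencies
        are at most driving/(2M), which keeps the driving harmonics
        Nyquist-safe and non-overlapping with complementary interference.
        """
        m = self.interference
        w_drive = (self.n_samples - 1) // (2 * m)
        w_comp_max = max(1, w_drive // (2 * m))
        return w_drive, w_comp_max


@dataclass
class EfastSample:
    """Sampled input matrix plus the bookkeeping needed to compute indices.

    ``matrix`` has one row per model run, ordered input-major then
    resample-major then curve position; ``x01`` holds the untransformed
    search-curve coordinates in [0, 1].
    """

    design: EfastDesign
    matrix: np.ndarray  # (n_inputs*n_resamples*n_samples, n_inputs)
    x01: np.ndarray  # same layout, before range mapping
    s: np.ndarray  # curve parameter, length n_samples
    frequencies: dict  # per driven input: frequency vector over all inputs

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    def block(self, driven_index: int, resample: int) -> slice:
        ns = self.design.n_samples
        nr = self.design.n_resamples
        start = (driven_index * nr + resample) * ns
        return slice(start, start + ns)


def _map_range(x01: np.ndarray, lo: float, hi: float, spacing: str) -> np.ndarray:
    if spacing == "log":
        return lo * (hi / lo) ** x01
    return lo + (hi - lo) * x01


def efast_sample(design: EfastDesign, seed: int = 0) -> EfastSample:
    """Generate the eFAST search-curve sample.

    Every input takes a turn as the driven input (including the dummy);
    for each resample a fresh random phase vector is drawn.  Distinct
    seeds give distinct phases but the same frequency assignment.
    """
    names = design.all_inputs
    k = len(names)
    w_drive, w_comp_max = design.frequencies()
    ns, nr, m = design.n_samples, design.n_resamples, design.interference
    if w_drive < 2 * m * w_comp_max:
        raise ValueError("driving frequency violates the interference criterion")
    rng = np.random.default_rng(seed)
    s = (2.0 * np.pi / ns) * (np.arange(ns) - (ns - 1) / 2.0)
    rows = np.empty((k * nr * ns, k))
    x01_rows = np.empty_like(rows)
    freq_map = {}
    for di in range(k):
        # complementary frequencies spread evenly over 1..w_comp_max so the
        # search curve covers the complementary subspace (a clustered
        # assignment yields closed low-order Lissajous curves that misestimate
        # interaction variance)
        freqs = np.empty(k, int)
        freqs[di] = w_drive
        if k > 1:
            comp = np.unique(
                np.round(np.linspace(1, w_comp_max, k - 1)).astype(int)
            )
            comp = [int(comp[j % len(comp)]) for j in range(k - 1)]
            freqs[[i for i in range(k) if i != di]] = comp
        freq_map[names[di]] = freqs
        for r in range(nr):
            phi = rng.uniform(0, 2 * np.pi, size=k)
            block = (di * nr + r) * ns
            for j in range(k):
                x = 0.5 + (1.0 / np.pi) * np.arcsin(
                    np.sin(freqs[j] * s + phi[j])
                )
                x01_rows[block : block + ns, j] = x
                if names[j] == DUMMY_NAME:
                    rows[block : block + ns, j] = x
                else:
                    lo, hi = design.bounds[names[j]]
                    rows[block : block + ns, j] = _map_range(
                        x, lo, hi, design.spacing
                    )
    return EfastSample(design, rows, x01_rows, s, freq_map)


@dataclass
class SensitivityResult:
    """First- and total-order indices per input (and output column)."""

    table: pd.DataFrame  # input, output, Si, ST, Si_sd, ST_sd
    resamples: dict  # (input, output) -> (Si array, ST array)
    design: EfastDesign

    def first_order(self, name: str, output=0) -> float:
        row = self.table[
            (self.table["input"] == name) & (self.table["output"] == output)
        ]
        return float(row["Si"].iloc[0])

    def total_order(self, name: str, output=0) -> float:
        row = self.table[
            (self.table["input"] == name) & (self.table["output"] == output)
        ]
        return float(row["ST"].iloc[0])


def _spectrum_power(y: np.ndarray, s: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Power 2*(A^2+B^2) at each integer frequency in ``freqs``."""
    ns = y.size
    out = np.empty(len(freqs))
    for i, w in enumerate(freqs):
        a = np.mean(y * np.cos(w * s))
        b = np.mean(y * np.sin(w * s))
        out[i] = 2.0 * (a * a + b * b)
    return out


def efast_indices(outputs: np.ndarray, sample: EfastSample) -> SensitivityResult:
    """Compute S_i and S_T from model outputs evaluated at the sample rows.

    ``outputs`` is (n_runs,) or (n_runs, n_outputs); indices are averaged
    over resample curves.  A zero-variance output yields zero indices and
    is flagged in the table (``degenerate`` column).
    """
    y = np.asarray(outputs, float)
    if y.ndim == 1:
        y = y[:, None]
    if not np.all(np.isfinite(y)):
        raise ValueError("outputs must be finite")
    design = sample.design
    names = design.all_inputs
    m = design.interference
    w_drive, w_comp_max = design.frequencies()
    rows = []
    resamples = {}
    for di, name in enumerate(names):
        for out_j in range(y.shape[1]):
            si_r = np.empty(design.n_resamples)
            st_r = np.empty(design.n_resamples)
            degenerate = False
            for r in range(design.n_resamples):
                yy = y[sample.block(di, r), out_j]
                yy = yy - yy.mean()
                total = np.var(yy)
                if total <= 0:
                    si_r[r] = st_r[r] = 0.0
                    degenerate = True
                    continue
                harmonics = np.arange(1, m + 1) * w_drive
                v_i = _spectrum_power(yy, sample.s, harmonics).sum()
                comp_freqs = np.arange(1, w_drive // 2 + 1)
                v_c = _spectrum_power(yy, sample.s, comp_freqs).sum()
                si_r[r] = v_i / total
                st_r[r] = 1.0 - v_c / total
            resamples[(name, out_j)] = (si_r.copy(), st_r.copy())
            rows.append(
                {
                    "input": name,
                    "output": out_j,
                    "Si": si_r.mean(),
                    "ST": st_r.mean(),
                    "Si_sd": si_r.std(ddof=1) if design.n_resamples > 1 else 0.0,
                    "ST_sd": st_r.std(ddof=1) if design.n_resamples > 1 else 0.0,
                    "degenerate": degenerate,
                }
            )
    return SensitivityResult(pd.DataFrame(rows), resamples, design)


def rank_influential(
    result: SensitivityResult,
    output=0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank inputs by total-order index with significance versus the dummy.

    An input is flagged influential when its S_T resamples exceed the
    dummy input's by a one-sided two-sample t-test at level ``alpha``.
    """
    if not result.design.include_dummy:
        raise ValueError("design carries no dummy input")
    dummy_st = result.resamples[(DUMMY_NAME, output)][1]
    rows = []
    for name in result.design.inputs:
        st = result.resamples[(name, output)][1]
        t = stats.ttest_ind(st, dummy_st, equal_var=False, alternative="greater")
        rows.append(
            {
                "input": name,
                "ST": float(st.mean()),
                "dummy_ST": float(dummy_st.mean()),
                "p_vs_dummy": float(t.pvalue),
                "influential": bool(t.pvalue < alpha),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("ST", ascending=False)
        .reset_index(drop=True)
    )
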