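"""Purity/ploidy estimation and allele-specific copy-number state fitting.

For a segment in state {n_A, n_B} in a tumour of purity phi and ploidy
psi (non-cancer cells assumed diploid), the expected corrected RDR and
mirrored BAF are

    r_hat = rbar * (phi (n_A + n_B) + 2 (1 - phi)) / (phi psi + 2 (1 - phi))
    b_hat = (phi n_B + (1 - phi)) / (phi (n_A + n_B) + 2 (1 - phi))

Sub-clonal states with clonality chi model the tumour cells lacking the
CNA as carrying the sample's modal state {m_A, m_B}:

    r_hat = rbar * (phi chi (n_A+n_B) + phi (1-chi)(m_A+m_B) + 2(1-phi))
                 / (phi psi + 2 (1 - phi))
    b_hat = (phi chi n_B + phi (1-chi) m_B + (1-phi)) / (same numerator
            denominator as r_hat without the rbar/psi scaling)

Goodness of fit is a variance-normalised mean squared error per segment,
summed over the RDR and BAF tracks, plus a flat penalty pi(chi) = 1 for
any sub-clonal state to discourage over-fitting.  Purity and ploidy are
found by grid search over the length-normalised genome MSE; because
high-ploidy solutions often fit marginally better without being real,
the *lowest-ploidy* sufficiently pronounced local minimum of the MSE
surface is selected rather than the global minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import SegmentData
from .welldata_io import CopyNumberProfile, WellDataError

CHI_GRID = (0.5, 0.6, 0.7, 0.8, 0.9)
SUBCLONAL_PENALTY = 1.0
SIGMA_FLOOR = 1e-6
DEFAULT_PHI_GRID = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
DEFAULT_PSI_GRID = np.round(np.arange(1.0, 8.0 + 1e-9, 0.05), 2)
MAX_TOTAL_COPY_CAP = 20


@dataclass(frozen=True)
class CopyNumberState:
    n_A: int
    n_B: int
    chi: float = 1.0

    def __post_init__(self):
        if self.n_B > self.n_A:
            raise WellDataError("canonical order requires n_A >= n_B")

    @property
    def total(self) -> int:
        return self.n_A + self.n_B


def expected_rdr(state: CopyNumberState, phi: float, psi: float, r_bar: float,
                 modal: tuple[int, int] | None = None) -> float:
    """Expected corrected RDR for a (possibly sub-clonal) state."""
    chi = state.chi
    if chi == 1.0:
        num = phi * state.total + 2.0 * (1.0 - phi)
    else:
        if modal is None:
            raise WellDataError("sub-clonal expectation requires the modal state")
        m_tot = modal[0] + modal[1]
        num = phi * chi * state.total + phi * (1 - chi) * m_tot + 2.0 * (1.0 - phi)
    return r_bar * num / (phi * psi + 2.0 * (1.0 - phi))


def expected_baf(state: CopyNumberState, phi: float,
                 modal: tuple[int, int] | None = None) -> float:
    """Expected mirrored BAF (<= 0.5 under canonical ordering).

    Undefined for a clonal {0, 0} state at phi = 1 (no DNA); such
    segments are fitted on the RDR term alone (NaN returned).
    """
    chi = state.chi
    if chi == 1.0:
        num = phi * state.n_B + (1.0 - phi)
        den = phi * state.total + 2.0 * (1.0 - phi)
    else:
        if modal is None:
            raise WellDataError("sub-clonal expectation requires the modal state")
        num = phi * chi * state.n_B + phi * (1 - chi) * modal[1] + (1.0 - phi)
        den = (phi * chi * state.total + phi * (1 - chi) * (modal[0] + modal[1])
               + 2.0 * (1.0 - phi))
    if den <= 0:
        return float("nan")
    return num / den


def estimate_noise(segments: list[SegmentData]) -> tuple[float, float]:
    """Pooled within-segment variance of RDR and mirrored BAF.

    The pooling is point-count weighted: sigma^2 = (sum of squared
    deviations from per-segment means) / (total points).  Values are
    floored at 1e-6 so degenerate (noise-free) inputs stay usable.
    """
    ss_r = n_r = ss_b = n_b = 0.0
    for seg in segments:
        if len(seg.r):
            ss_r += float(((seg.r - seg.r.mean()) ** 2).sum())
            n_r += len(seg.r)
        if seg.has_baf:
            wmean = float((seg.b * seg.b_weight).sum() / seg.b_weight.sum())
            ss_b += float(((seg.b - wmean) ** 2).sum())
            n_b += len(seg.b)
    sigma_r = ss_r / n_r if n_r else 0.0
    sigma_b = ss_b / n_b if n_b else 0.0
    return max(sigma_r, SIGMA_FLOOR), max(sigma_b, SIGMA_FLOOR)


def max_total_copy(segments: list[SegmentData], phi: float, psi: float,
                   r_bar: float, cap: int = MAX_TOTAL_COPY_CAP) -> int:
    """Smallest total copy number whose expected RDR exceeds every
    segment-mean corrected RDR in the genome (capped)."""
    r_max = max((float(seg.r.mean()) for seg in segments if len(seg.r)),
                default=r_bar)
    for n in range(1, cap + 1):
        if expected_rdr(CopyNumberState(n, 0), phi, psi, r_bar) > r_max:
            return n
    return cap


def enumerate_states(n_max: int) -> list[tuple[int, int]]:
    """All canonical {n_A, n_B} with n_A >= n_B and n_A + n_B <= n_max,
    ordered by (total, -n_B) to make parsimony tie-breaks positional."""
    states = []
    for tot in range(n_max + 1):
        for n_b in range(tot // 2, -1, -1):
            states.append((tot - n_b, n_b))
    return states


@dataclass
class SegmentStats:
    """Sufficient statistics of one segment for MSE evaluation."""

    n_r: int
    mean_r: float
    ss_r: float    # within-segment sum of squares, RDR
    n_b: int
    mean_b: float
    ss_b: float
    length: float


def _segment_stats(segments: list[SegmentData]) -> list[SegmentStats]:
    out = []
    for seg in segments:
        n_r = len(seg.r)
        mean_r = float(seg.r.mean()) if n_r else np.nan
        ss_r = float(((seg.r - mean_r) ** 2).sum()) if n_r else 0.0
        n_b = len(seg.b)
        mean_b = float(seg.b.mean()) if n_b else np.nan
        ss_b = float(((seg.b - mean_b) ** 2).sum()) if n_b else 0.0
        out.append(SegmentStats(n_r, mean_r, ss_r, n_b, mean_b, ss_b,
                                float(seg.length)))
    return out


def segment_mse(seg: SegmentData, state: CopyNumberState, phi: float,
                psi: float, r_bar: float, sigma2: tuple[float, float],
                modal: tuple[int, int] | None = None,
                penalty: float = SUBCLONAL_PENALTY) -> float:
    """Per-segment MSE: variance-normalised RDR term + BAF term
    (+ pi(chi) for sub-clonal states)."""
    sigma_r, sigma_b = sigma2
    total = 0.0
    if len(seg.r):
        r_hat = expected_rdr(state, phi, psi, r_bar, modal)
        total += float(((seg.r - r_hat) ** 2).mean()) / sigma_r
    if seg.has_baf:
        b_hat = expected_baf(state, phi, modal)
        if np.isfinite(b_hat):
            total += float(((seg.b - b_hat) ** 2).mean()) / sigma_b
    if state.chi != 1.0:
        total += penalty
    return total


@dataclass
class FitSolution:
    purity: float
    ploidy: float
    states: list[CopyNumberState]
    modal: tuple[int, int]
    sigma2: tuple[float, float]
    mse: float
    mse_grid: pd.DataFrame  # columns phi, psi, mse


def _grid_mse(stats: list[SegmentStats], phi_grid: np.ndarray,
              psi_grid: np.ndarray, r_bar: float,
              sigma2: tuple[float, float]) -> np.ndarray:
    """Genome MSE surface, shape (len(phi_grid), len(psi_grid)).

    Vectorised over states and segments: the per-segment MSE decomposes
    into a state-independent within-variance term plus the squared
    offset of the segment mean from the state expectation, so only the
    sufficient statistics enter.
    """
    sigma_r, sigma_b = sigma2
    n_r = np.array([s.n_r for s in stats])
    has_r = n_r > 0
    mean_r = np.array([s.mean_r if s.n_r else 0.0 for s in stats])
    ssn_r = np.array([s.ss_r / s.n_r if s.n_r else 0.0 for s in stats])
    has_b = np.array([s.n_b > 0 for s in stats])
    mean_b = np.array([s.mean_b if s.n_b else 0.0 for s in stats])
    ssn_b = np.array([s.ss_b / s.n_b if s.n_b else 0.0 for s in stats])
    lengths = np.array([s.length for s in stats])
    r_max = np.nanmax(np.where(n_r > 0, mean_r, -np.inf))

    states = np.array(enumerate_states(MAX_TOTAL_COPY_CAP))  # (S, 2)
    tot = states.sum(axis=1).astype(float)
    n_b_arr = states[:, 1].astype(float)

    surface = np.empty((len(phi_grid), len(psi_grid)))
    base = ssn_r / sigma_r + np.where(has_b, ssn_b / sigma_b, 0.0)  # (K,)
    for a, phi in enumerate(phi_grid):
        mix_den = phi * tot + 2.0 * (1.0 - phi)           # (S,)
        b_hat = (phi * n_b_arr + (1.0 - phi)) / np.maximum(mix_den, 1e-12)
        b_term = np.where(has_b[None, :],
                          (mean_b[None, :] - b_hat[:, None]) ** 2 / sigma_b,
                          0.0)                             # (S, K)
        for c, psi in enumerate(psi_grid):
            scale = r_bar / (phi * psi + 2.0 * (1.0 - phi))
            r_hat = mix_den * scale                        # (S,)
            r_term = np.where(has_r[None, :],
                              (mean_r[None, :] - r_hat[:, None]) ** 2 / sigma_r,
                              0.0)
            mse_sk = r_term + b_term + base[None, :]       # (S, K)
            # states beyond the genome-wide maximum RDR are not considered
            allowed = tot <= max(_total_limit(r_hat, r_max, tot), 1)
            mse_sk[~allowed] = np.inf
            seg_mse = mse_sk.min(axis=0)                   # (K,)
            surface[a, c] = float((lengths * seg_mse).sum() / lengths.sum())
    return surface


def _total_limit(r_hat: np.ndarray, r_max: float, tot: np.ndarray) -> int:
    """Smallest total copy with expected RDR above the observed maximum."""
    above = tot[r_hat > r_max]
    return int(above.min()) if len(above) else MAX_TOTAL_COPY_CAP


def fit_states(segments: list[SegmentData], phi: float, psi: float,
               r_bar: float, sigma2: tuple[float, float],
               allow_subclonal: bool = False,
               modal: tuple[int, int] | None = None,
               n_max: int | None = None,
               penalty: float = SUBCLONAL_PENALTY) -> list[CopyNumberState]:
    """Assign each segment its minimum-MSE copy-number state.

    With ``allow_subclonal`` the candidate set is expanded by every
    state crossed with chi in {0.5, ..., 0.9} (the modal state itself
    excluded — a sub-clonal 'change' to the background state is not an
    event), each carrying the flat penalty.  Ties break toward lower
    total copy, then higher clonality, then higher n_B.
    """
    if allow_subclonal and modal is None:
        raise WellDataError("sub-clonal fitting requires the modal state")
    if n_max is None:
        n_max = max_total_copy(segments, phi, psi, r_bar)
    candidates: list[CopyNumberState] = []
    for (na, nb) in enumerate_states(n_max):
        candidates.append(CopyNumberState(na, nb, 1.0))
        if allow_subclonal and (na, nb) != tuple(modal or ()):
            for chi in sorted(CHI_GRID, reverse=True):
                candidates.append(CopyNumberState(na, nb, chi))
    # canonical tie-break order: (total, 1-chi, -n_B); first minimum wins
    candidates.sort(key=lambda s: (s.total, 1.0 - s.chi, -s.n_B))
    out = []
    for seg in segments:
        best, best_mse = None, np.inf
        for st in candidates:
            m = segment_mse(seg, st, phi, psi, r_bar, sigma2, modal, penalty)
            if m < best_mse - 1e-12:
                best, best_mse = st, m
        out.append(best)
    return out


def modal_state(segments: list[SegmentData],
                states: list[CopyNumberState]) -> tuple[int, int]:
    """Genomic-length mode of the fitted clonal states."""
    lengths: dict[tuple[int, int], float] = {}
    for seg, st in zip(segments, states):
        key = (st.n_A, st.n_B)
        lengths[key] = lengths.get(key, 0.0) + seg.length
    return max(lengths.items(), key=lambda kv: kv[1])[0]


def genome_mse(segments: list[SegmentData], states: list[CopyNumberState],
               phi: float, psi: float, r_bar: float,
               sigma2: tuple[float, float],
               modal: tuple[int, int] | None = None) -> float:
    """Length-normalised genome MSE for explicit per-segment states."""
    num = den = 0.0
    for seg, st in zip(segments, states):
        num += seg.length * segment_mse(seg, st, phi, psi, r_bar, sigma2, modal)
        den += seg.length
    return num / den


def _local_minima(surface: np.ndarray) -> list[tuple[int, int]]:
    """Grid cells strictly smaller than all existing neighbours (8-conn)."""
    n, m = surface.shape
    minima = []
    for a in range(n):
        for c in range(m):
            v = surface[a, c]
            ok = True
            for da in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if da == dc == 0:
                        continue
                    aa, cc = a + da, c + dc
                    if 0 <= aa < n and 0 <= cc < m and surface[aa, cc] <= v:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                minima.append((a, c))
    return minima


def grid_search(segments: list[SegmentData], r_bar: float,
                phi_grid: np.ndarray = DEFAULT_PHI_GRID,
                psi_grid: np.ndarray = DEFAULT_PSI_GRID,
                kappa: float = 1.2,
                sigma2: tuple[float, float] | None = None) -> FitSolution:
    """Estimate purity and ploidy by MSE grid search.

    Every (phi, psi) pair receives the genome MSE of its best clonal
    per-segment states.  Among the local minima of the surface whose MSE
    is within ``kappa`` times the global minimum, the one with lowest
    ploidy wins — the guard against spuriously well-fitting high-ploidy
    solutions.
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    psi_grid = np.asarray(psi_grid, dtype=float)
    if len(phi_grid) == 0 or len(psi_grid) == 0:
        raise WellDataError("purity/ploidy grid is empty")
    if not segments:
        raise WellDataError("no segments to fit")
    if sigma2 is None:
        sigma2 = estimate_noise(segments)
    stats = _segment_stats(segments)
    surface = _grid_mse(stats, phi_grid, psi_grid, r_bar, sigma2)
    global_min = float(surface.min())
    minima = _local_minima(surface)
    if not minima:
        minima = [tuple(np.unravel_index(int(surface.argmin()), surface.shape))]
    eligible = [(a, c) for (a, c) in minima
                if surface[a, c] <= kappa * max(global_min, 1e-300)]
    if not eligible:
        eligible = minima
    # lowest ploidy among eligible minima; MSE then purity break ties
    a, c = min(eligible, key=lambda ac: (psi_grid[ac[1]], surface[ac],
                                         phi_grid[ac[0]]))
    phi, psi = float(phi_grid[a]), float(psi_grid[c])
    states = fit_states(segments, phi, psi, r_bar, sigma2,
                        allow_subclonal=False)
    modal = modal_state(segments, states)
    mse = genome_mse(segments, states, phi, psi, r_bar, sigma2)
    grid_df = pd.DataFrame({
        "phi": np.repeat(phi_grid, len(psi_grid)),
        "psi": np.tile(psi_grid, len(phi_grid)),
        "mse": surface.ravel(),
    })
    return FitSolution(purity=phi, ploidy=psi, states=states, modal=modal,
                       sigma2=sigma2, mse=mse, mse_grid=grid_df)


def fit_profile(segments: list[SegmentData], r_bar: float,
                phi_grid: np.ndarray = DEFAULT_PHI_GRID,
                psi_grid: np.ndarray = DEFAULT_PSI_GRID,
                kappa: float = 1.2,
                allow_subclonal: bool = True) -> tuple[CopyNumberProfile, FitSolution]:
    """Grid search then (optionally sub-clonal) state fitting; returns
    the final profile and the full solution object."""
    sol = grid_search(segments, r_bar, phi_grid, psi_grid, kappa)
    states = sol.states
    if allow_subclonal:
        states = fit_states(segments, sol.purity, sol.ploidy, r_bar,
                            sol.sigma2, allow_subclonal=True, modal=sol.modal)
    rows = [(seg.chrom, seg.start, seg.end, st.n_A, st.n_B, st.chi)
            for seg, st in zip(segments, states)]
    profile = CopyNumberProfile(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "n_A", "n_B",
                                    "clonality"]),
        purity=sol.purity, ploidy=sol.ploidy, mse=sol.mse)
    sol.states = states
    return profile, sol
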