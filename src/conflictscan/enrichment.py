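"""Statistical layer: trait enrichment, positional clustering, length peaks.

The association of a system with the multicellular habit is tested with the
hypergeometric distribution: with q = organisms carrying the system that
are multicellular, m = multicellular organisms, n = non-multicellular
organisms and k = organisms carrying the system, the reported p-value is
the upper tail P(X >= q) -- the probability of drawing at least q
multicellular organisms in k draws without replacement.  Tails are summed
in log space, so p-values far below the smallest normal double remain
meaningful as log-probabilities.

Chromosomal position bias is tested by binning normalized anchor positions
(stop coordinate over replicon length) into equal intervals (default 20)
and applying the chi-square goodness-of-fit test against uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist


@dataclass(frozen=True)
class EnrichmentInput:
    q: int  # multicellular organisms with the system
    m: int  # multicellular organisms in the universe
    n: int  # non-multicellular organisms in the universe
    k: int  # organisms with the system

    def __post_init__(self) -> None:
        if not (0 <= self.q <= min(self.k, self.m)):
            raise ValueError(f"need 0 <= q <= min(k, m); got {self}")
        if self.k > self.m + self.n:
            raise ValueError(f"k exceeds universe: {self}")
        if self.k - self.q > self.n:
            raise ValueError(f"k - q exceeds n: {self}")


@dataclass
class EnrichmentResult:
    system: str
    inp: EnrichmentInput | None
    p_upper: float | None
    log10_p: float | None
    fold: float | None


@dataclass
class PositionDistribution:
    positions: list[float]
    n_bins: int
    observed: list[int]
    chi2: float
    df: int
    p: float
    folded: bool


@dataclass
class LengthDistribution:
    lengths: list[int]
    bin_width: int
    bin_edges: list[float]
    counts: list[int]
    smoothed: list[float]
    peak_centers: list[float]


# ---------------------------------------------------------------------------
# hypergeometric tails (log-space)


def _log_hypergeom_pmf(i: np.ndarray, m: int, n: int, k: int) -> np.ndarray:
    return (
        gammaln(m + 1)
        - gammaln(i + 1)
        - gammaln(m - i + 1)
        + gammaln(n + 1)
        - gammaln(k - i + 1)
        - gammaln(n - k + i + 1)
        - (gammaln(m + n + 1) - gammaln(k + 1) - gammaln(m + n - k + 1))
    )


def log_hypergeometric_upper_tail(q: int, m: int, n: int, k: int) -> float:
    """Natural log of P(X >= q) for X ~ Hypergeom(m+n, m, k)."""
    EnrichmentInput(q=q, m=m, n=n, k=k)
    if q == 0:
        return 0.0
    i = np.arange(q, min(m, k) + 1)
    return float(logsumexp(_log_hypergeom_pmf(i, m, n, k)))


def hypergeometric_upper_tail(q: int, m: int, n: int, k: int) -> float:
    """P(X >= q); summed in log space, exp'd at the end (may be subnormal)."""
    return min(float(np.exp(log_hypergeometric_upper_tail(q, m, n, k))), 1.0)


def hypergeometric_lower_tail(q: int, m: int, n: int, k: int) -> float:
    """P(X <= q) for X ~ Hypergeom(m+n, m, k)."""
    if q >= min(m, k):
        return 1.0
    lo = max(0, k - n)
    i = np.arange(lo, q + 1)
    if i.size == 0:
        return 0.0
    return min(float(np.exp(logsumexp(_log_hypergeom_pmf(i, m, n, k)))), 1.0)


# ---------------------------------------------------------------------------
# multicellularity enrichment


def multicell_enrichment(
    instances: Sequence,
    metadata: Mapping[str, Mapping[str, str]],
) -> list[EnrichmentResult]:
    """Per system type, the hypergeometric association with multicellularity.

    ``metadata`` maps genome_id to a record with a ``multicellular`` flag in
    {"True", "False", "NA"}.  NA organisms are excluded from the universe
    and from the presence counts; presence is per organism (>= 1 instance),
    not per instance.
    """
    flags = {gid: rec["multicellular"] for gid, rec in metadata.items()}
    universe = {gid for gid, f in flags.items() if f in ("True", "False")}
    m = sum(1 for gid in universe if flags[gid] == "True")
    n = len(universe) - m
    presence: dict[str, set[str]] = {}
    for inst in instances:
        presence.setdefault(inst.system_type, set()).add(inst.genome_id)
    results = []
    for system in sorted(presence):
        orgs = presence[system] & universe
        k = len(orgs)
        if k == 0:
            results.append(EnrichmentResult(system, None, None, None, None))
            continue
        q = sum(1 for gid in orgs if flags[gid] == "True")
        logp = log_hypergeometric_upper_tail(q, m, n, k)
        results.append(
            EnrichmentResult(
                system=system,
                inp=EnrichmentInput(q=q, m=m, n=n, k=k),
                p_upper=min(float(np.exp(logp)), 1.0),
                log10_p=logp / np.log(10),
                fold=(q / k) / (m / (m + n)) if m else None,
            )
        )
    return results


def recover_multicellular_count(
    rows: Sequence[tuple[int, int, float]], total: int
) -> int:
    """Invert printed (q, k, p) enrichment rows for the shared trait count m.

    Scans every feasible m and returns the one minimizing the summed squared
    log-p discrepancy across rows -- useful when a study prints per-system
    q, k and p but not the trait margin of its organism universe.
    """
    qmax = max(q for q, _k, _p in rows)
    best_m, best_err = None, None
    for m in range(qmax, total):
        err = 0.0
        ok = True
        for q, k, p in rows:
            n = total - m
            if k - q > n:
                ok = False
                break
            err += (log_hypergeometric_upper_tail(q, m, n, k) - np.log(p)) ** 2
        if ok and (best_err is None or err < best_err):
            best_m, best_err = m, err
    if best_m is None:
        raise ValueError("no feasible m")
    return best_m


# ---------------------------------------------------------------------------
# positional clustering


def position_chi_square(
    positions: Sequence[float],
    n_bins: int = 20,
    fold: bool = False,
) -> PositionDistribution:
    """Chi-square test of positional uniformity over equal genome intervals.

    ``positions`` are normalized anchor stops in [0, 1].  With ``fold`` the
    two replicon arms are superimposed (x -> min(x, 1-x), binned over
    [0, 0.5]), reflecting symmetry of the two arms around the center.
    """
    xs = [float(x) for x in positions]
    if not xs:
        raise ValueError("no positions given")
    if any(not (0.0 <= x <= 1.0) for x in xs):
        raise ValueError("positions must be normalized into [0, 1]")
    if fold:
        xs = [min(x, 1.0 - x) for x in xs]
        hi = 0.5
    else:
        hi = 1.0
    observed, _edges = np.histogram(xs, bins=n_bins, range=(0.0, hi))
    n = len(xs)
    expected = n / n_bins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = n_bins - 1
    p = float(chi2_dist.sf(chi2, df))
    return PositionDistribution(
        positions=xs,
        n_bins=n_bins,
        observed=observed.tolist(),
        chi2=chi2,
        df=df,
        p=p,
        folded=fold,
    )


def positions_from_instances(instances: Sequence) -> list[float]:
    return [inst.anchor_stop / inst.replicon_length for inst in instances]


# ---------------------------------------------------------------------------
# length multimodality


def length_peaks(
    lengths: Sequence[int],
    bin_width: int = 50,
    min_peak_fraction: float = 0.05,
) -> LengthDistribution:
    """Histogram peaks of a protein length distribution.

    The histogram (fixed bin width) is smoothed with a 3-bin moving average;
    peaks are strict local maxima of the smoothed profile whose height
    reaches ``min_peak_fraction`` of the sample size.  Centers are bin
    midpoints.
    """
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        raise ValueError("no lengths given")
    lo = (lengths[0] // bin_width) * bin_width
    hi = ((lengths[-1] // bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(lengths, bins=edges)
    padded = np.concatenate([[counts[0]], counts, [counts[-1]]])
    smoothed = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    thresh = min_peak_fraction * len(lengths)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peaks = []
    for i in range(len(smoothed)):
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[i + 1] if i < len(smoothed) - 1 else -np.inf
        if smoothed[i] > left and smoothed[i] > right and smoothed[i] >= thresh:
            peaks.append(float(centers[i]))
    if not peaks and len(smoothed) == 1:
        peaks = [float(centers[0])]
    return LengthDistribution(
        lengths=list(lengths),
        bin_width=bin_width,
        bin_edges=edges.tolist(),
        counts=counts.tolist(),
        smoothed=smoothed.tolist(),
        peak_centers=peaks,
    )
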