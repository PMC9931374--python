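"""Probabilistic quantization of omics measurements into trinary states.

Continuous measurements (mRNA, CNV, methylation, miRNA, phosphoprotein) are
modelled as noisy read-outs of a discrete hidden state x in {-1, 0, +1}
(down / unchanged / up).  Each measurement is mapped to a posterior
probability vector (p(x=-1), p(x=0), p(x=+1)) through its within-feature
empirical CDF value u, so the mapping depends on the data only through
ranks and is invariant to monotone transforms of the raw scale.

Discrete alteration codes (somatic mutation, SNP genotypes) are represented
with all probability mass on the reported code: for mutations 0/1/2 denote
silent/missense/nonsense, for SNPs 0/1/2 count minor alleles.

CNV probes are quantized with cut points re-fit to the empirical fraction
of amplification/deletion calls, then merged into segments wherever the
per-sample posteriors of consecutive probes are close in L1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

UNINFORMATIVE = np.full(3, 1.0 / 3.0)

#: recognised feature types and whether their state axis is trinary (-1,0,+1)
#: or a raw code axis (0,1,2)
FEATURE_TYPES = (
    "mRNA",
    "cisCNV",
    "transCNV",
    "mutation",
    "methylation",
    "miRNA",
    "phospho",
    "SNP",
)
DISCRETE_TYPES = ("mutation", "SNP")


@dataclass(frozen=True)
class QuantizeParams:
    """Parameters of the two-ramp logistic quantizer.

    ``q_low``/``q_high`` are the CDF cut points of the down/up states and
    ``slope`` the logistic steepness on the u axis.  The default tertile cut
    points make the three hidden states a priori equiprobable, matching the
    uniform trinary null of the association model; CNV layers instead re-fit
    the cut points to the empirical amplification/deletion rates.
    """

    q_low: float = 1.0 / 3.0
    q_high: float = 2.0 / 3.0
    slope: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_low <= self.q_high <= 1.0:
            raise ValueError("require 0 <= q_low <= q_high <= 1")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


@dataclass
class QuantizedMatrix:
    """Per-feature, per-sample state posteriors for one omics layer.

    ``probs`` has shape (n_features, n_samples, 3).  For trinary layers the
    last axis is states (-1, 0, +1); for mutation/SNP layers it indexes the
    raw codes (0, 1, 2).
    """

    features: list[str]
    samples: list[str]
    probs: np.ndarray
    ftype: str
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.features), len(self.samples), 3):
            raise ValueError("probs shape inconsistent with feature/sample ids")
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")

    def row(self, feature: str) -> np.ndarray:
        return self.probs[self.features.index(feature)]

    def expected_state(self) -> pd.DataFrame:
        """E[x] per (feature, sample): p(+1) - p(-1) on the trinary axis."""
        if self.ftype in DISCRETE_TYPES:
            raise ValueError("expected_state is defined for trinary layers only")
        return pd.DataFrame(
            self.probs[:, :, 2] - self.probs[:, :, 0],
            index=self.features,
            columns=self.samples,
        )


@dataclass
class CnvSegment:
    """Contiguous run of CNV probes sharing one per-sample state posterior."""

    chrom: str
    start: int  # first probe index, inclusive
    end: int  # last probe index, inclusive
    probs: np.ndarray  # (n_samples, 3) averaged posterior

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def ecdf_values(values: np.ndarray) -> np.ndarray:
    """Mid-rank empirical CDF of the non-missing entries, NaN preserved."""
    values = np.asarray(values, dtype=float)
    u = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    n = int(mask.sum())
    if n:
        ranks = pd.Series(values[mask]).rank(method="average").to_numpy()
        u[mask] = (ranks - 0.5) / n
    return u


def state_probabilities(u: np.ndarray, params: QuantizeParams) -> np.ndarray:
    """Map CDF values u in [0,1] to trinary state posteriors.

    p(+1) is nondecreasing and p(-1) nonincreasing in u; missing u gives the
    uninformative vector.
    """
    u = np.asarray(u, dtype=float)
    p_plus = _sigmoid(params.slope * (u - params.q_high))
    p_minus = _sigmoid(params.slope * (params.q_low - u))
    p_zero = 1.0 - p_plus - p_minus
    probs = np.stack([p_minus, p_zero, p_plus], axis=-1)
    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=-1, keepdims=True)
    probs[~np.isfinite(u)] = UNINFORMATIVE
    return probs


def quantize_continuous(
    values: np.ndarray, params: QuantizeParams | None = None
) -> np.ndarray:
    """Quantize one feature's per-sample continuous values.

    Requires at least 3 non-missing values; raises ``ValueError`` when every
    value is missing (the caller flags and skips such features).
    """
    params = params or QuantizeParams()
    values = np.asarray(values, dtype=float)
    n_obs = int(np.isfinite(values).sum())
    if n_obs == 0:
        raise ValueError("all values missing")
    if n_obs < 3:
        raise ValueError("need >= 3 non-missing values to quantize")
    return state_probabilities(ecdf_values(values), params)


def fit_cnv_params(
    values: np.ndarray,
    amp_threshold: float = 0.3,
    del_threshold: float = -0.3,
    base: QuantizeParams | None = None,
) -> QuantizeParams:
    """Re-fit quantizer cut points to empirical amplification/deletion rates.

    The cut points are moved so that the expected mass of the +1 (-1) state
    matches the fraction of values above ``amp_threshold`` (below
    ``del_threshold``) on the raw copy-number scale.
    """
    base = base or QuantizeParams()
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return base
    amp = float(np.mean(values > amp_threshold))
    dele = float(np.mean(values < del_threshold))
    # keep a sliver of the 0 state even for saturated inputs
    q_high = float(np.clip(1.0 - amp, 0.02, 0.98))
    q_low = float(np.clip(dele, 0.02, q_high))
    return replace(base, q_low=q_low, q_high=q_high)


def encode_discrete(codes: np.ndarray, kind: str) -> np.ndarray:
    """Encode mutation / SNP codes as point-mass probability vectors.

    The state axis is the raw code axis {0, 1, 2}; missing codes map to the
    uniform vector.  Out-of-range codes raise ``ValueError``.
    """
    if kind not in DISCRETE_TYPES:
        raise ValueError(f"kind must be one of {DISCRETE_TYPES}, got {kind!r}")
    codes = np.asarray(codes, dtype=float)
    probs = np.zeros(codes.shape + (3,))
    missing = ~np.isfinite(codes)
    valid = ~missing
    if valid.any():
        iv = codes[valid]
        if np.any((iv < 0) | (iv > 2) | (iv != np.round(iv))):
            bad = int(np.flatnonzero(valid)[np.argmax((iv < 0) | (iv > 2) | (iv != np.round(iv)))])
            raise ValueError(f"{kind} code out of range {{0,1,2}} at position {bad}")
        probs[valid, iv.astype(int)] = 1.0
    probs[missing] = UNINFORMATIVE
    return probs


def quantize_matrix(
    data: pd.DataFrame,
    ftype: str,
    params: QuantizeParams | None = None,
    fit_cnv: bool = True,
) -> QuantizedMatrix:
    """Quantize a features x samples DataFrame of one omics layer.

    Continuous layers go through the logistic-ramp quantizer (CNV layers with
    empirically re-fit cut points unless ``fit_cnv`` is false); mutation/SNP
    layers through the point-mass encoder.  All-missing features are skipped
    and recorded in ``QuantizedMatrix.skipped``.
    """
    if ftype not in FEATURE_TYPES:
        raise ValueError(f"unknown feature type {ftype!r}")
    features: list[str] = []
    skipped: list[str] = []
    rows: list[np.ndarray] = []
    for fid, row in data.iterrows():
        values = row.to_numpy(dtype=float)
        if ftype in DISCRETE_TYPES:
            rows.append(encode_discrete(values, ftype))
            features.append(str(fid))
            continue
        try:
            if ftype in ("cisCNV", "transCNV") and fit_cnv:
                p = fit_cnv_params(values, base=params or QuantizeParams())
            else:
                p = params or QuantizeParams()
            rows.append(quantize_continuous(values, p))
            features.append(str(fid))
        except ValueError:
            skipped.append(str(fid))
    probs = np.stack(rows) if rows else np.empty((0, data.shape[1], 3))
    return QuantizedMatrix(
        features=features,
        samples=[str(c) for c in data.columns],
        probs=probs,
        ftype=ftype,
        skipped=skipped,
    )


def merge_cnv_segments(
    probe_probs: np.ndarray,
    chrom: str = "chr1",
    tolerance: float = 0.1,
) -> list[CnvSegment]:
    """Merge position-ordered CNV probe posteriors into segments.

    A probe joins the running segment when the mean (over samples) L1
    distance between its posterior and the running segment average is at
    most ``tolerance``; otherwise it starts a new segment.  Segment
    posteriors are per-sample averages of their member probes, and the
    segments tile the probe list.
    """
    probe_probs = np.asarray(probe_probs, dtype=float)
    if probe_probs.ndim != 3 or probe_probs.shape[0] == 0:
        raise ValueError("probe_probs must be a non-empty (probes, samples, 3) array")
    segments: list[CnvSegment] = []
    start = 0
    acc = probe_probs[0].copy()
    for i in range(1, probe_probs.shape[0]):
        mean_probs = acc / (i - start)
        l1 = float(np.abs(probe_probs[i] - mean_probs).sum(axis=-1).mean())
        if l1 <= tolerance:
            acc += probe_probs[i]
        else:
            segments.append(CnvSegment(chrom, start, i - 1, acc / (i - start)))
            start = i
            acc = probe_probs[i].copy()
    segments.append(
        CnvSegment(chrom, start, probe_probs.shape[0] - 1, acc / (probe_probs.shape[0] - start))
    )
    return segments
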