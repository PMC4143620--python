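"""Pairwise IBD inference from unphased genotypes under a Markov IBD process.

The latent process for a pair of individuals is a continuous-time Markov chain
on the number of allele pairs shared identical by descent, k ∈ {0, 1, 2}. It
is built from two independent two-state component chains, one per haplotype
pair, each with stationary IBD probability ``beta`` and relaxation rate
``alpha`` per centimorgan:

    P_component(d) = Pi + exp(-alpha * d) * (I - Pi),   Pi rows = (1-beta, beta)

The three-state chain is the symmetrized product of the two components, so its
stationary distribution is ((1-β)², 2β(1-β), β²) and Chapman–Kolmogorov holds
exactly. This condensed genotype-level state space is a deliberate
simplification appropriate for non-inbred, pedigree-unrelated pairs, where
only the Any-IBD / Not-IBD contrast is consumed downstream.

Emissions are the classical IBS-given-IBD genotype-pair probabilities under
Hardy–Weinberg equilibrium and marker independence given the state, with a
per-individual genotype-error mixture. Decoding is posterior (scaled
forward–backward), never Viterbi: a state is *called* at a marker only when
its posterior reaches the calling threshold ``kappa``; otherwise the marker is
NO_CALL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

# call codes
NOT_IBD, ANY_IBD_1, ANY_IBD_2, NO_CALL = 0, 1, 2, 3
# call classes for segments / summaries
CLASS_NOT, CLASS_ANY, CLASS_NOCALL = "not_ibd", "any_ibd", "no_call"

_CALL_CLASS = {NOT_IBD: CLASS_NOT, ANY_IBD_1: CLASS_ANY,
               ANY_IBD_2: CLASS_ANY, NO_CALL: CLASS_NOCALL}


@dataclass(frozen=True)
class IBDModelParams:
    """Parameters of the latent IBD process and the calling rule.

    alpha
        Rate of change of IBD state along the chromosome, per cM.
    beta
        Pointwise probability that one haplotype pair is IBD (the
        time-depth of IBD sought; small beta = recent IBD only).
    epsilon
        Per-marker, per-individual genotype error probability.
    kappa
        Posterior probability a state must reach to be called.
    """

    alpha: float = 0.05
    beta: float = 0.01
    epsilon: float = 0.01
    kappa: float = 0.9

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if not 0.5 < self.kappa <= 1:
            raise ValueError("kappa must be in (0.5, 1]")

    @property
    def stationary(self) -> np.ndarray:
        b = self.beta
        return np.array([(1 - b) ** 2, 2 * b * (1 - b), b * b])


@dataclass
class IBDTrack:
    """Posterior IBD decoding for one individual pair along one chromosome."""

    pair: tuple[str, str]
    posteriors: np.ndarray          # (n_markers, 3), rows sum to 1
    calls: np.ndarray               # (n_markers,) int codes, see module constants
    segments: pd.DataFrame          # class, start/end cm and bp, n_markers
    loglik: float

    @property
    def call_classes(self) -> np.ndarray:
        return np.array([_CALL_CLASS[c] for c in self.calls])


@dataclass
class SharingSummary:
    """Marker-proportion and segment-length summary of a group of tracks."""

    group: str
    mean_prop: dict[str, float]     # over markers x pairs; sums to 1
    mean_len: dict[str, float]      # mean segment length in cM; NaN if no segment
    n_pairs: int
    n_markers: int


def _component_transition(alpha: float, beta: float, d_cm) -> np.ndarray:
    """Two-state haplotype-pair chain P(d) = Pi + e^(-alpha d) (I - Pi)."""
    e = np.exp(-alpha * np.asarray(d_cm, dtype=float))
    p01 = beta * (1.0 - e)          # notIBD -> IBD
    p10 = (1.0 - beta) * (1.0 - e)  # IBD -> notIBD
    out = np.empty(np.shape(e) + (2, 2))
    out[..., 0, 0] = 1.0 - p01
    out[..., 0, 1] = p01
    out[..., 1, 0] = p10
    out[..., 1, 1] = 1.0 - p10
    return out


def transition_matrix(params: IBDModelParams, d_cm: float) -> np.ndarray:
    """3x3 transition matrix over a genetic distance of ``d_cm`` centimorgans.

    Product of two independent component chains, collapsed to the count of
    IBD haplotype pairs. ``d_cm = 0`` gives the identity; ``d_cm -> inf``
    gives rows equal to the stationary distribution.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    T = _transition_stack(params, np.atleast_1d(d))
    return T[0] if d.ndim == 0 else T


def _transition_stack(params: IBDModelParams, d_cm: np.ndarray) -> np.ndarray:
    """(M, 3, 3) transition matrices for a vector of distances."""
    c = _component_transition(params.alpha, params.beta, d_cm)
    p00, p01 = c[..., 0, 0], c[..., 0, 1]
    p10, p11 = c[..., 1, 0], c[..., 1, 1]
    T = np.empty(d_cm.shape + (3, 3))
    T[..., 0, 0] = p00 * p00
    T[..., 0, 1] = 2 * p00 * p01
    T[..., 0, 2] = p01 * p01
    T[..., 1, 0] = p10 * p00
    T[..., 1, 1] = p10 * p01 + p11 * p00
    T[..., 1, 2] = p11 * p01
    T[..., 2, 0] = p10 * p10
    T[..., 2, 1] = 2 * p11 * p10
    T[..., 2, 2] = p11 * p11
    return T


def emission_probs(k: int, p: float, epsilon: float = 0.0) -> np.ndarray:
    """P(ordered genotype pair | IBD state k) as a 3x3 array [g_a, g_b].

    Genotypes are alt-allele counts 0/1/2 at a biallelic marker with alt
    frequency ``p``, under HWE. State 0: independent genotypes; state 2:
    identical genotypes drawn once from HWE; state 1: one shared allele plus
    one free allele each. Genotype error mixes toward the independent table:
    ``E_k = (1-eps)^2 E_k + (1-(1-eps)^2) E_0``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return _emission_table(np.array([p]), epsilon)[0, k]


def _emission_table(p: np.ndarray, epsilon: float) -> np.ndarray:
    """(M, 3 states, 3, 3) emission tables; monomorphic markers emit 1."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=-1)      # (M, 3)
    allele = np.stack([q, p], axis=-1)                      # (M, 2)

    E0 = hwe[:, :, None] * hwe[:, None, :]
    E2 = np.zeros_like(E0)
    for g in range(3):
        E2[:, g, g] = hwe[:, g]
    # state 1: shared allele a, free alleles b1, b2; genotype = a + b
    E1 = np.zeros_like(E0)
    for a in (0, 1):
        for b1 in (0, 1):
            for b2 in (0, 1):
                E1[:, a + b1, a + b2] += allele[:, a] * allele[:, b1] * allele[:, b2]

    keep = (1.0 - epsilon) ** 2
    E = np.stack([E0, keep * E1 + (1 - keep) * E0, keep * E2 + (1 - keep) * E0], axis=1)
    mono = (p <= 0.0) | (p >= 1.0)
    E[mono] = 1.0  # uninformative: skipped rather than erroring
    return E


def _pair_emissions(E: np.ndarray, ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Per-marker emission vectors (P, M, 3); missing genotypes (<0) emit 1."""
    ga = np.atleast_2d(ga)
    gb = np.atleast_2d(gb)
    M = E.shape[0]
    gaf = np.where(ga < 0, 0, ga)
    gbf = np.where(gb < 0, 0, gb)
    # advanced indices at axes 0, 2, 3 with a slice at axis 1 -> (P, M, 3)
    out = E[np.arange(M)[None, :], :, gaf, gbf]
    miss = (ga < 0) | (gb < 0)
    out[miss] = 1.0
    return out


def _forward_backward(emis: np.ndarray, trans: np.ndarray,
                      pi0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of pairs.

    emis: (P, M, 3); trans: (M-1, 3, 3) shared across pairs.
    Returns posteriors (P, M, 3) and log-likelihood (P,).
    """
    P, M, S = emis.shape
    alpha = np.empty((P, M, S))
    scales = np.empty((P, M))
    a = pi0[None, :] * emis[:, 0, :]
    c = a.sum(axis=1)
    c[c == 0.0] = np.finfo(float).tiny
    alpha[:, 0] = a / c[:, None]
    scales[:, 0] = c
    for m in range(1, M):
        a = np.einsum("ps,st->pt", alpha[:, m - 1], trans[m - 1]) * emis[:, m]
        c = a.sum(axis=1)
        c[c == 0.0] = np.finfo(float).tiny
        alpha[:, m] = a / c[:, None]
        scales[:, m] = c

    beta = np.ones((P, S))
    post = np.empty((P, M, S))
    post[:, M - 1] = alpha[:, M - 1]
    for m in range(M - 2, -1, -1):
        beta = np.einsum("st,pt->ps", trans[m], emis[:, m + 1] * beta) / scales[:, m + 1, None]
        g = alpha[:, m] * beta
        post[:, m] = g / g.sum(axis=1, keepdims=True)
    return post, np.log(scales).sum(axis=1)


def _calls_from_posteriors(post: np.ndarray, kappa: float) -> np.ndarray:
    best = post.argmax(axis=-1)
    called = post.max(axis=-1) >= kappa
    return np.where(called, best, NO_CALL).astype(np.int8)


def _segments(calls: np.ndarray, cm: np.ndarray, bp: np.ndarray) -> pd.DataFrame:
    """Maximal runs of the same call class; length = cM span of the run."""
    classes = np.array([_CALL_CLASS[c] for c in calls])
    rows = []
    start = 0
    for m in range(1, len(calls) + 1):
        if m == len(calls) or classes[m] != classes[start]:
            rows.append({
                "state_class": classes[start],
                "start_cm": float(cm[start]), "end_cm": float(cm[m - 1]),
                "start_bp": int(bp[start]), "end_bp": int(bp[m - 1]),
                "n_markers": m - start,
            })
            start = m
    return pd.DataFrame(rows, columns=["state_class", "start_cm", "end_cm",
                                       "start_bp", "end_bp", "n_markers"])


def _panel_arrays(panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract cm, bp, freq from a marker panel; fall back to 1 cM/Mb."""
    bp = panel["bp"].to_numpy(dtype=float)
    if "cm" in panel.columns and panel["cm"].notna().all():
        cm = panel["cm"].to_numpy(dtype=float)
    else:
        cm = bp / 1e6
    if np.any(np.diff(cm) < 0):
        raise ValueError("panel cM positions must be non-decreasing")
    freq = panel["freq"].to_numpy(dtype=float)
    return cm, bp, freq


def posterior_decode(params: IBDModelParams, panel: pd.DataFrame,
                     ga: np.ndarray, gb: np.ndarray,
                     pair: tuple[str, str] = ("a", "b")) -> IBDTrack:
    """Posterior-decode the IBD state sequence for one genotype pair.

    ``panel`` needs columns ``bp``, ``freq`` and optionally ``cm`` (missing
    cM falls back to 1 cM per Mb). ``ga``/``gb`` are alt-allele counts with
    ``-1`` for missing. Missing genotypes emit probability 1 in every state.
    """
    tracks = posterior_decode_pairs(params, panel, np.asarray(ga)[None, :],
                                    np.asarray(gb)[None, :], [pair])
    return tracks[0]


def posterior_decode_pairs(params: IBDModelParams, panel: pd.DataFrame,
                           ga: np.ndarray, gb: np.ndarray,
                           pairs: Sequence[tuple[str, str]],
                           chunk: int = 2048) -> list[IBDTrack]:
    """Vectorized posterior decoding for a batch of pairs on a shared panel.

    ``ga``/``gb`` have shape (n_pairs, n_markers); transition matrices are
    shared across pairs, so the forward-backward sweep is vectorized over
    pairs in chunks to bound memory.
    """
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    cm, bp, freq = _panel_arrays(panel)
    M = len(panel)
    if ga.shape[1] != M or gb.shape[1] != M:
        raise ValueError("genotype series length does not match panel")
    E = _emission_table(freq, params.epsilon)
    trans = _transition_stack(params, np.diff(cm))
    pi0 = params.stationary

    tracks: list[IBDTrack] = []
    for lo in range(0, ga.shape[0], chunk):
        hi = min(lo + chunk, ga.shape[0])
        emis = _pair_emissions(E, ga[lo:hi], gb[lo:hi])
        post, ll = _forward_backward(emis, trans, pi0)
        for i in range(hi - lo):
            calls = _calls_from_posteriors(post[i], params.kappa)
            tracks.append(IBDTrack(
                pair=tuple(pairs[lo + i]),
                posteriors=post[i],
                calls=calls,
                segments=_segments(calls, cm, bp),
                loglik=float(ll[i]),
            ))
    return tracks


def sharing_summary(tracks: Sequence[IBDTrack], group: str) -> SharingSummary:
    """Mean call-class proportions and mean segment lengths over a group.

    Proportions are taken jointly over all markers and all pairs; segment
    lengths (cM) are averaged over all segments of each class across pairs.
    A class with no segments reports NaN, not 0.
    """
    if not tracks:
        raise ValueError("sharing_summary needs at least one track")
    all_classes = np.concatenate([t.call_classes for t in tracks])
    total = all_classes.size
    prop = {c: float((all_classes == c).sum()) / total
            for c in (CLASS_ANY, CLASS_NOT, CLASS_NOCALL)}
    segs = pd.concat([t.segments for t in tracks], ignore_index=True)
    mean_len = {}
    for c in (CLASS_ANY, CLASS_NOT, CLASS_NOCALL):
        sub = segs[segs["state_class"] == c]
        mean_len[c] = float((sub["end_cm"] - sub["start_cm"]).mean()) if len(sub) else float("nan")
    return SharingSummary(group=group, mean_prop=prop, mean_len=mean_len,
                          n_pairs=len(tracks), n_markers=tracks[0].posteriors.shape[0])


def summary_table(summaries: Sequence[SharingSummary]) -> pd.DataFrame:
    """Stack group summaries into a table of proportions and segment lengths."""
    rows = []
    for s in summaries:
        rows.append({
            "group": s.group,
            "prop_any_ibd": s.mean_prop[CLASS_ANY],
            "prop_not_ibd": s.mean_prop[CLASS_NOT],
            "prop_no_call": s.mean_prop[CLASS_NOCALL],
            "len_any_ibd": s.mean_len[CLASS_ANY],
            "len_not_ibd": s.mean_len[CLASS_NOT],
            "len_no_call": s.mean_len[CLASS_NOCALL],
            "n_pairs": s.n_pairs,
        })
    return pd.DataFrame(rows)
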