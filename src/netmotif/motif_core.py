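"""ZOOPS-model motif discovery and genome-wide PWM scanning.

Discovery fits a "zero or one occurrence per sequence" mixture by
expectation-maximization: each input sequence either contains one motif site
(at any position, on either strand) or is pure background.  Candidate seeds
are input w-mers; each seed gets one EM step, the best seed is refined to
convergence, and found sites are probabilistically erased before the next
motif is sought.  Motif significance is a seeded Monte-Carlo E-value over
composition-preserving shuffles of the input.

Scanning scores every genome window on both strands with integer-discretized
log-odds, converts scores to p-values by exact dynamic-programming
convolution under the background's order-0 marginal, and adjusts with
Benjamini-Hochberg q-values over all scored windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from netmotif.genome_io import (
    BASES,
    Genome,
    MarkovBackground,
    encode_dna,
    revcomp,
)

log = logging.getLogger(__name__)

DEFAULT_WIDTHS = (8, 10, 12, 14, 16, 18, 20)

_EM_TOL = 1e-4
_EM_MAX_ITER = 200
_MAX_SEEDS = 500
_SEED_MATCH_PROB = 0.7  # seed base probability when initializing from a w-mer
_PWM_PSEUDO = 0.01
_GAMMA_BOUNDS = (1e-3, 1.0 - 1e-3)


class MotifInputError(ValueError):
    """Raised when discovery input is unusable (too few/short sequences)."""


@dataclass
class PWM:
    """Per-position base probabilities (width x 4, columns A,C,G,T)."""

    probs: np.ndarray
    pseudocount: float = _PWM_PSEUDO

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.pseudocount)

    @classmethod
    def from_sites(cls, sites: list[str], pseudocount: float = _PWM_PSEUDO) -> "PWM":
        width = len(sites[0])
        counts = np.full((width, 4), pseudocount)
        for site in sites:
            codes = encode_dna(site)
            for k, c in enumerate(codes):
                if c >= 0:
                    counts[k, c] += 1
        return cls(counts / counts.sum(axis=1, keepdims=True), pseudocount)

    @classmethod
    def from_consensus(
        cls, pattern: str, strength: float = 0.94, pseudocount: float = _PWM_PSEUDO
    ) -> "PWM":
        """Build a PWM from an A/C/G/T/N pattern; N columns are uniform."""
        rows = []
        for ch in pattern.upper():
            if ch == "N":
                rows.append(np.full(4, 0.25))
            elif ch in BASES:
                row = np.full(4, (1 - strength) / 3)
                row[BASES.index(ch)] = strength
                rows.append(row)
            else:
                raise ValueError(f"unsupported consensus character {ch!r}")
        return cls(np.array(rows), pseudocount)


@dataclass
class DiscoveredMotif:
    """A discovery result: PWM, E-value, and the ordered per-input score list.

    ``site_scores`` holds exactly one entry per input sequence as
    (locus_tag, best site log-odds score in bits, or None when the posterior
    says the sequence has no site), sorted by descending score with absent
    entries last; ties break on locus_tag.  The order of this list is what
    downstream index bookkeeping refers to.
    """

    pwm: PWM
    evalue: float
    site_scores: list[tuple[str, float | None]] = field(default_factory=list)

    def index_of(self, locus_tag: str) -> int:
        for i, (tag, _score) in enumerate(self.site_scores):
            if tag == locus_tag:
                return i
        return -1


@dataclass(frozen=True)
class Occurrence:
    """One scan hit: a genome window clearing the p-value threshold."""

    start: int  # 0-based offset on the forward strand
    strand: int  # +1 / -1
    sequence: str  # matched word as read on its strand
    score: float  # log-odds, bits
    pvalue: float
    qvalue: float

    @property
    def width(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def consensus(pwm: PWM, threshold: float = 0.7) -> str:
    """IUPAC-lite consensus: the majority base when its probability clears
    ``threshold``, else N."""
    out = []
    for row in pwm.probs:
        best = int(np.argmax(row))
        out.append(BASES[best] if row[best] >= threshold else "N")
    return "".join(out)


# ---------------------------------------------------------------------------
# ZOOPS EM machinery
#
# All placements (window positions x strands, over all sequences) are packed
# into one matrix of base codes; scoring any PWM over all placements is then
# a single fancy-indexing sum, and scoring many seed PWMs at once is a
# one-hot matrix product.


class _ZoopsData:
    """Packed placement matrices for one motif width."""

    def __init__(self, sequences: list[tuple[str, str]], width: int, both_strands: bool):
        self.width = width
        self.ids = [sid for sid, _ in sequences]
        self.seqs = [s.upper() for _, s in sequences]
        self.n_seq = len(self.seqs)
        windows = []
        placement_seq = []  # sequence index per placement
        placement_pos = []  # start on the forward strand of the input sequence
        placement_strand = []
        for i, seq in enumerate(self.seqs):
            codes = encode_dna(seq)
            m = len(seq) - width + 1
            if m <= 0:
                continue
            idx = np.arange(m)[:, None] + np.arange(width)[None, :]
            win = codes[idx]
            ok = (win >= 0).all(axis=1)
            windows.append(win[ok])
            placement_seq.append(np.full(int(ok.sum()), i))
            placement_pos.append(np.arange(m)[ok])
            placement_strand.append(np.ones(int(ok.sum()), dtype=np.int8))
            if both_strands:
                rc_codes = encode_dna(revcomp(seq))
                rc_win = rc_codes[idx]
                rc_ok = (rc_win >= 0).all(axis=1)
                windows.append(rc_win[rc_ok])
                placement_seq.append(np.full(int(rc_ok.sum()), i))
                # start of the matched window on the forward strand
                placement_pos.append((len(seq) - width - np.arange(m))[rc_ok])
                placement_strand.append(-np.ones(int(rc_ok.sum()), dtype=np.int8))
        if windows:
            self.windows = np.concatenate(windows)
            self.placement_seq = np.concatenate(placement_seq)
            self.placement_pos = np.concatenate(placement_pos)
            self.placement_strand = np.concatenate(placement_strand)
        else:
            self.windows = np.empty((0, width), dtype=np.int8)
            self.placement_seq = np.empty(0, dtype=int)
            self.placement_pos = np.empty(0, dtype=int)
            self.placement_strand = np.empty(0, dtype=np.int8)
        order = np.argsort(self.placement_seq, kind="stable")
        self.windows = self.windows[order]
        self.placement_seq = self.placement_seq[order]
        self.placement_pos = self.placement_pos[order]
        self.placement_strand = self.placement_strand[order]
        # per-sequence slices (sequences with zero placements get empty slices)
        self.seq_starts = np.searchsorted(self.placement_seq, np.arange(self.n_seq))
        self.seq_stops = np.searchsorted(self.placement_seq, np.arange(self.n_seq) + 1)
        self.m_per_seq = self.seq_stops - self.seq_starts
        self.usable = self.m_per_seq > 0
        # one-hot encoding for batched seed scoring and fast PWM scoring
        n = self.windows.shape[0]
        self.onehot = np.zeros((n, width * 4), dtype=np.float32)
        flat = np.arange(width) * 4 + self.windows
        rows = np.repeat(np.arange(n), width)
        self.onehot[rows, flat.ravel()] = 1.0
        self.onehot64 = self.onehot.astype(np.float64)
        # background log-probability of each placement's letters
        counts = np.zeros(4)
        for b in range(4):
            counts[b] = sum(int(np.sum(encode_dna(s) == b)) for s in self.seqs)
        # both-strand symmetrized composition
        comp = counts + counts[::-1]
        self.bg = (comp + 1.0) / (comp.sum() + 4.0)
        self.log_bg_window = np.log(self.bg)[self.windows].sum(axis=1)

    def seq_logsumexp(self, values: np.ndarray) -> np.ndarray:
        """Per-sequence logsumexp over placements; -inf for empty slices.

        ``values`` has placements on axis 0 (any trailing axes allowed).
        Placements are contiguous per sequence, so segment reductions via
        ``reduceat`` are exact.
        """
        out = np.full((self.n_seq,) + values.shape[1:], -np.inf)
        nonempty = np.nonzero(self.m_per_seq > 0)[0]
        if nonempty.size == 0 or values.shape[0] == 0:
            return out
        starts = self.seq_starts[nonempty]
        counts = np.diff(np.append(starts, values.shape[0]))
        mx = np.maximum.reduceat(values, starts, axis=0)
        shifted = np.exp(values - np.repeat(mx, counts, axis=0))
        sums = np.add.reduceat(shifted, starts, axis=0)
        out[nonempty] = mx + np.log(sums)
        return out


def _zoops_loglik_terms(
    data: _ZoopsData, llr: np.ndarray, gamma: float, log_weight: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """E-step quantities for one PWM.

    Returns (placement posteriors Z, per-sequence site probabilities Q,
    log-likelihood relative to the all-background model).
    """
    with np.errstate(divide="ignore"):
        log_m = np.where(data.m_per_seq > 0, np.log(np.maximum(data.m_per_seq, 1)), 0.0)
    # log numerator per placement: log(gamma/m_i) + llr + log erase-weight
    log_num = llr + log_weight + np.log(gamma) - log_m[data.placement_seq]
    per_seq = data.seq_logsumexp(log_num)  # log(gamma/m * sum LR)
    log_denom = np.logaddexp(np.log1p(-gamma), per_seq)
    log_denom = np.where(data.usable, log_denom, 0.0)
    Z = np.exp(log_num - log_denom[data.placement_seq])
    Q = np.where(data.usable, np.exp(per_seq - log_denom), 0.0)
    loglik = float(np.sum(log_denom[data.usable]))
    return Z, Q, loglik


def _m_step(data: _ZoopsData, Z: np.ndarray) -> tuple[np.ndarray, float]:
    """Update letter probabilities and the site prior from posteriors."""
    counts = (Z.astype(np.float32) @ data.onehot).reshape(data.width, 4).astype(float)
    counts += _PWM_PSEUDO
    probs = counts / counts.sum(axis=1, keepdims=True)
    n_usable = int(data.usable.sum())
    gamma = float(np.clip(Z.sum() / max(n_usable, 1), *_GAMMA_BOUNDS))
    return probs, gamma


def _llr_for(data: _ZoopsData, probs: np.ndarray) -> np.ndarray:
    return data.onehot64 @ np.log(probs).ravel() - data.log_bg_window


def _em_refine(
    data: _ZoopsData,
    probs: np.ndarray,
    gamma: float,
    log_weight: np.ndarray,
    max_iter: int = _EM_MAX_ITER,
    tol: float = _EM_TOL,
) -> tuple[np.ndarray, float, float]:
    """Run EM to convergence; returns (probs, gamma, final log-likelihood)."""
    prev = -np.inf
    loglik = prev
    for _ in range(max_iter):
        llr = _llr_for(data, probs)
        Z, _Q, loglik = _zoops_loglik_terms(data, llr, gamma, log_weight)
        probs, gamma = _m_step(data, Z)
        if abs(loglik - prev) < tol:
            break
        prev = loglik
    return probs, gamma, loglik


def _seed_search(
    data: _ZoopsData,
    log_weight: np.ndarray,
    max_seeds: int = _MAX_SEEDS,
    gamma0: float = 0.5,
    full_rank: bool = True,
) -> tuple[np.ndarray, float]:
    """Evaluate input w-mers as seeds (one EM step each); return the probs
    and gamma of the best seed after its single update.

    With ``full_rank`` seeds are ranked by their post-update likelihood
    (one extra scoring pass over all seeds); without it they are ranked by
    the pre-update likelihood and only the winner gets the M-step -- cheaper,
    used for the shuffle-null searches inside the E-value estimate.
    """
    n = data.windows.shape[0]
    if n == 0:
        raise MotifInputError("no usable placements at this width")
    stride = max(1, -(-n // max_seeds))  # ceil division
    seed_idx = np.arange(0, n, stride)
    # batched one-step evaluation via one-hot matmul:
    # llr(seed s, placement p) = match_count * log(p_match/p_other)
    #                            + w*log(p_other) - log bg(window p)
    p_match, p_other = _SEED_MATCH_PROB, (1 - _SEED_MATCH_PROB) / 3
    match = data.onehot @ data.onehot[seed_idx].T  # (n, S) match counts
    llr = (
        match * (np.log(p_match) - np.log(p_other))
        + data.width * np.log(p_other)
        - data.log_bg_window[:, None]
    )
    log_num = (
        llr
        + log_weight[:, None]
        + np.log(gamma0)
        - np.log(np.maximum(data.m_per_seq, 1))[data.placement_seq, None]
    )
    per_seq = data.seq_logsumexp(log_num)
    log_denom = np.logaddexp(np.log1p(-gamma0), per_seq)
    log_denom = np.where(data.usable[:, None], log_denom, 0.0)
    n_usable = int(data.usable.sum())
    if not full_rank:
        # rank by pre-update likelihood; M-step for the winner only
        logliks0 = np.where(data.usable[:, None], log_denom, 0.0).sum(axis=0)
        best = int(np.argmax(logliks0))
        z_best = np.exp(log_num[:, best] - log_denom[data.placement_seq, best])
        probs, gamma = _m_step(data, z_best)
        return probs, gamma
    Z = np.exp(log_num - log_denom[data.placement_seq])
    # M-step for every seed at once, then re-score once to rank seeds
    counts = (Z.astype(np.float32).T @ data.onehot).astype(float)  # (S, 4w)
    counts = counts.reshape(len(seed_idx), data.width, 4) + _PWM_PSEUDO
    probs_all = counts / counts.sum(axis=2, keepdims=True)
    logf_flat = np.log(probs_all).reshape(len(seed_idx), -1).T  # (4w, S)
    llr2 = data.onehot @ logf_flat - data.log_bg_window[:, None]
    gammas = np.clip(Z.sum(axis=0) / max(n_usable, 1), *_GAMMA_BOUNDS)
    log_num2 = (
        llr2
        + log_weight[:, None]
        + np.log(gammas)[None, :]
        - np.log(np.maximum(data.m_per_seq, 1))[data.placement_seq, None]
    )
    per_seq2 = data.seq_logsumexp(log_num2)
    log_denom2 = np.logaddexp(np.log1p(-gammas)[None, :], per_seq2)
    logliks = np.where(data.usable[:, None], log_denom2, 0.0).sum(axis=0)
    best = int(np.argmax(logliks))
    return probs_all[best], float(gammas[best])


def _fit_width(
    data: _ZoopsData, log_weight: np.ndarray
) -> tuple[np.ndarray, float, float]:
    probs, gamma = _seed_search(data, log_weight)
    return _em_refine(data, probs, gamma, log_weight)


def _zoops_statistic(data: _ZoopsData, probs: np.ndarray, log_weight=None) -> float:
    """ZOOPS log-likelihood ratio of a fixed PWM (site prior re-estimated
    by a short EM over gamma only)."""
    if log_weight is None:
        log_weight = np.zeros(data.windows.shape[0])
    gamma = 0.5
    loglik = -np.inf
    llr = _llr_for(data, probs)
    for _ in range(20):
        Z, _Q, loglik = _zoops_loglik_terms(data, llr, gamma, log_weight)
        n_usable = int(data.usable.sum())
        new_gamma = float(np.clip(Z.sum() / max(n_usable, 1), *_GAMMA_BOUNDS))
        if abs(new_gamma - gamma) < 1e-6:
            gamma = new_gamma
            break
        gamma = new_gamma
    Z, _Q, loglik = _zoops_loglik_terms(data, llr, gamma, log_weight)
    return loglik


def _shuffle_sequences(
    sequences: list[tuple[str, str]], rng: np.random.Generator
) -> list[tuple[str, str]]:
    out = []
    for sid, seq in sequences:
        chars = np.array(list(seq))
        out.append((sid, "".join(chars[rng.permutation(len(chars))])))
    return out


def motif_evalue(
    pwm: PWM,
    sequences: list[tuple[str, str]],
    n_shuffles: int = 20,
    seed: int = 0,
    both_strands: bool = True,
) -> float:
    """Monte-Carlo E-value: expected count of equal-or-better ZOOPS
    log-likelihood-ratio alignments in composition-preserving shuffles.

    Estimated as (exceedances + 1) / n_shuffles, one motif searched per
    shuffle.  Deterministic given the seed.
    """
    ev, _z = _motif_evalue_z(pwm, sequences, n_shuffles, seed, both_strands)
    return ev


def _motif_evalue_z(
    pwm: PWM,
    sequences: list[tuple[str, str]],
    n_shuffles: int = 20,
    seed: int = 0,
    both_strands: bool = True,
) -> tuple[float, float]:
    """E-value plus a z-score of the observed statistic against the shuffle
    distribution (used only as a deterministic tie-break between widths)."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    width = pwm.width
    usable = [(sid, s) for sid, s in sequences if len(s) >= width]
    if len(usable) < 2:
        raise MotifInputError("fewer than 2 sequences at least as long as the motif")
    data = _ZoopsData(usable, width, both_strands)
    observed = _zoops_statistic(data, pwm.probs)
    rng = np.random.default_rng(seed)
    null_stats = []
    for _ in range(n_shuffles):
        shuffled = _shuffle_sequences(usable, rng)
        sdata = _ZoopsData(shuffled, width, both_strands)
        zero = np.zeros(sdata.windows.shape[0])
        try:
            probs, gamma = _seed_search(sdata, zero, max_seeds=50, full_rank=False)
            probs, gamma, loglik = _em_refine(sdata, probs, gamma, zero, max_iter=25)
        except MotifInputError:
            loglik = 0.0
        null_stats.append(loglik)
    null = np.array(null_stats)
    exceed = int(np.sum(null >= observed))
    evalue = (exceed + 1) / n_shuffles
    sd = float(null.std())
    z = (observed - float(null.mean())) / sd if sd > 0 else np.inf
    return float(evalue), float(z)


def _site_scores(
    data: _ZoopsData, probs: np.ndarray, gamma: float, log_weight: np.ndarray
) -> list[tuple[str, float | None]]:
    """Ordered per-input-sequence score list (ZOOPS: best site or absent)."""
    llr = _llr_for(data, probs)
    _Z, Q, _loglik = _zoops_loglik_terms(data, llr, gamma, log_weight)
    entries: list[tuple[str, float | None]] = []
    for i, sid in enumerate(data.ids):
        lo, hi = data.seq_starts[i], data.seq_stops[i]
        if hi > lo and Q[i] >= 0.5:
            best = float(llr[lo:hi].max() / np.log(2))  # bits
            entries.append((sid, best))
        else:
            entries.append((sid, None))
    entries.sort(key=lambda e: (-(e[1] if e[1] is not None else -np.inf), e[0]))
    return entries


def _erase(
    erase_logs: list[np.ndarray], data: _ZoopsData, Z: np.ndarray
) -> None:
    """Probabilistically erase found sites: each letter position covered by a
    placement with posterior Z keeps survival probability *= (1 - Z)."""
    for p in range(data.windows.shape[0]):
        z = Z[p]
        if z < 1e-3:
            continue
        i = data.placement_seq[p]
        start = data.placement_pos[p]
        surv = max(1.0 - z, 1e-6)
        erase_logs[i][start : start + data.width] += np.log(surv)


def _placement_log_weight(erase_logs: list[np.ndarray], data: _ZoopsData) -> np.ndarray:
    """Placement prior weight = product of letter survival over its window."""
    out = np.empty(data.windows.shape[0])
    for i, elog in enumerate(erase_logs):
        lo, hi = data.seq_starts[i], data.seq_stops[i]
        if hi <= lo:
            continue
        csum = np.concatenate(([0.0], np.cumsum(elog)))
        starts = data.placement_pos[lo:hi]
        out[lo:hi] = csum[starts + data.width] - csum[starts]
    return out


def _column_info(probs: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Per-column KL information against the background, in bits."""
    return (probs * (np.log2(probs + 1e-12) - np.log2(bg)[None, :])).sum(axis=1)


def _weak_edge_columns(probs: np.ndarray, bg: np.ndarray) -> int:
    """Count uninformative padding columns at the motif edges.

    A column is padding when it carries less than half the motif's median
    per-column information; interior weak columns (spacers in gapped or
    palindromic motifs) are not counted.
    """
    info = _column_info(probs, bg)
    threshold = 0.5 * float(np.median(info))
    left = 0
    while left < len(info) and info[left] < threshold:
        left += 1
    right = 0
    while right < len(info) - left and info[len(info) - 1 - right] < threshold:
        right += 1
    return left + right


def discover_zoops(
    sequences: list[tuple[str, str]],
    nmotifs: int = 5,
    both_strands: bool = True,
    evalue_threshold: float = 1000.0,
    widths: tuple[int, ...] = DEFAULT_WIDTHS,
    seed: int = 0,
    n_shuffles: int = 20,
) -> list[DiscoveredMotif]:
    """Discover up to ``nmotifs`` ZOOPS motifs in the input sequences.

    Per candidate width the best EM fit is kept; across widths the motif
    with the lowest Monte-Carlo E-value wins (z-score tie-break).  Sites of
    each found motif are probabilistically erased before the next search.
    Motifs with E-value above ``evalue_threshold`` are discarded; the result
    is ordered by ascending E-value.
    """
    sequences = [(sid, s.upper()) for sid, s in sequences]
    widths = tuple(sorted(set(widths)))
    if len(sequences) < 2:
        raise MotifInputError("motif discovery needs at least 2 sequences")
    if not any(len(s) >= min(widths) for _, s in sequences):
        raise MotifInputError("no sequence is as long as the smallest width")

    data_by_width: dict[int, _ZoopsData] = {}
    for w in widths:
        usable = [(sid, s) for sid, s in sequences if len(s) >= w]
        if len(usable) >= 2:
            data_by_width[w] = _ZoopsData(sequences, w, both_strands)
    if not data_by_width:
        raise MotifInputError("fewer than 2 sequences usable at every width")

    erase_logs = [np.zeros(len(s)) for _, s in sequences]
    motifs: list[DiscoveredMotif] = []
    for motif_i in range(nmotifs):
        candidates = []
        for w, data in data_by_width.items():
            log_weight = _placement_log_weight(erase_logs, data)
            try:
                probs, gamma, _loglik = _fit_width(data, log_weight)
            except MotifInputError:
                continue
            ev, _z = _motif_evalue_z(
                PWM(probs), sequences, n_shuffles=n_shuffles,
                seed=seed + 1009 * motif_i + w, both_strands=both_strands,
            )
            weak = _weak_edge_columns(probs, data.bg)
            candidates.append((ev, weak, -w, probs, gamma))
        if not candidates:
            break
        # lowest E-value wins; E-value ties (the Monte-Carlo estimate has
        # resolution 1/n_shuffles) break toward the widest candidate without
        # uninformative edge padding
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        ev, _weak, neg_w, probs, gamma = candidates[0]
        w = -neg_w
        data = data_by_width[w]
        log_weight = _placement_log_weight(erase_logs, data)
        llr = _llr_for(data, probs)
        Z, _Q, _ll = _zoops_loglik_terms(data, llr, gamma, log_weight)
        _erase(erase_logs, data, Z)
        if ev > evalue_threshold:
            log.info("motif %d E-value %.3g above threshold; stopping", motif_i, ev)
            break
        motifs.append(
            DiscoveredMotif(
                pwm=PWM(probs),
                evalue=ev,
                site_scores=_site_scores(data, probs, gamma, log_weight),
            )
        )
    motifs.sort(key=lambda m: m.evalue)
    return motifs


# ---------------------------------------------------------------------------
# PWM p-values and genome scanning

SCORE_SCALE = 1000


class ScoreDistribution:
    """Exact distribution of integer-discretized PWM log-odds scores under
    an i.i.d. background (the order-0 marginal)."""

    def __init__(self, pwm: PWM, background: MarkovBackground):
        bg = np.asarray(background.marginal, dtype=float)
        if np.any(bg <= 0):
            raise ValueError("background marginal has a zero-probability base")
        probs = pwm.probs + pwm.pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        logodds = np.log2(probs / bg[None, :])
        self.score_matrix = np.round(logodds * SCORE_SCALE).astype(np.int64)
        self.bg = bg
        # DP convolution, position by position, over an offset integer array
        mins = self.score_matrix.min(axis=1)
        maxs = self.score_matrix.max(axis=1)
        self.min_score = int(mins.sum())
        self.max_score = int(maxs.sum())
        # the array base must cover every intermediate partial sum, including
        # the initial 0 (relevant when all entries share one sign)
        self.base = int(np.minimum(mins, 0).sum())
        top = int(np.maximum(maxs, 0).sum())
        size = top - self.base + 1
        pmf = np.zeros(size)
        pmf[-self.base] = 1.0
        for k in range(pwm.width):
            nxt = np.zeros(size)
            for b in range(4):
                s = int(self.score_matrix[k, b])
                p = bg[b]
                if s > 0:
                    nxt[s:] += pmf[: size - s] * p
                elif s < 0:
                    nxt[:s] += pmf[-s:] * p
                else:
                    nxt += pmf * p
            pmf = nxt
        self.pmf = pmf
        tail = np.cumsum(pmf[::-1])[::-1]
        self.tail = np.minimum(tail, 1.0)

    def pvalue(self, score: int) -> float:
        """Pr(score' >= score) under the background."""
        idx = score - self.base
        if idx <= 0:
            return 1.0
        if idx >= len(self.tail):
            return 0.0
        return float(self.tail[idx])

    def pvalues(self, scores: np.ndarray) -> np.ndarray:
        raw = scores - self.base
        idx = np.clip(raw, 0, len(self.tail) - 1)
        out = self.tail[idx]
        out = np.where(raw <= 0, 1.0, out)
        out = np.where(raw >= len(self.tail), 0.0, out)
        return out


def score_distribution(pwm: PWM, background: MarkovBackground) -> ScoreDistribution:
    """Exact DP distribution of integer-scaled log-odds scores; supports
    ``pvalue(score)`` lookups for the scan stage."""
    return ScoreDistribution(pwm, background)


def bh_qvalues(pvalues, m: int) -> list[float]:
    """Benjamini-Hochberg step-up q-values for an ascending p-value list,
    with ``m`` hypotheses (may exceed the list length when only the smallest
    p-values were kept)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(np.diff(p) < 0):
        raise ValueError("p-values must be sorted ascending")
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    ranks = np.arange(1, p.size + 1)
    q = m * p / ranks
    q = np.minimum.accumulate(q[::-1])[::-1]
    return list(np.minimum(q, 1.0))


def _window_scores(codes: np.ndarray, score_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores for every window start; second array flags windows
    containing ambiguous bases (to be excluded)."""
    width = score_matrix.shape[0]
    n = len(codes) - width + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for k in range(width):
        scores += score_matrix[k, safe[k : k + n]]
        invalid |= codes[k : k + n] < 0
    return scores, invalid


def scan(
    genome: Genome,
    pwm: PWM,
    background: MarkovBackground,
    p_threshold: float = 1e-4,
) -> list[Occurrence]:
    """Scan every genome window on both strands with the PWM.

    Windows with p-value <= ``p_threshold`` are emitted, sorted ascending by
    p-value (ties by start, then + before - strand).  q-values are
    Benjamini-Hochberg over all scored windows on both strands, so they do
    not depend on the report threshold.
    """
    width = pwm.width
    if len(genome) < width:
        raise ValueError("genome shorter than PWM width")
    dist = score_distribution(pwm, background)
    rc_matrix = dist.score_matrix[::-1, ::-1]
    codes = encode_dna(genome.sequence)

    fwd_scores, fwd_invalid = _window_scores(codes, dist.score_matrix)
    rev_scores, rev_invalid = _window_scores(codes, rc_matrix)

    records = []  # (pvalue, start, strand_order, strand, score_int)
    n_tests = 0
    for strand, scores, invalid in ((1, fwd_scores, fwd_invalid), (-1, rev_scores, rev_invalid)):
        valid = ~invalid
        n_tests += int(valid.sum())
        pvals = dist.pvalues(scores)
        keep = valid & (pvals <= p_threshold)
        for start in np.nonzero(keep)[0]:
            records.append((float(pvals[start]), int(start), 0 if strand == 1 else 1,
                            strand, int(scores[start])))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    qvals = bh_qvalues([r[0] for r in records], m=n_tests)
    out = []
    for (pvalue, start, _so, strand, score_int), q in zip(records, qvals):
        word = genome.sequence[start : start + width]
        if strand == -1:
            word = revcomp(word)
        out.append(
            Occurrence(
                start=start,
                strand=strand,
                sequence=word,
                score=score_int / SCORE_SCALE,
                pvalue=pvalue,
                qvalue=float(q),
            )
        )
    return out


# ---------------------------------------------------------------------------
# MEME-minimal-style text output

def write_motifs(motifs: list[DiscoveredMotif], path, background: MarkovBackground | None = None) -> None:
    """Write motifs as minimal-format letter-probability matrix blocks."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = background.marginal if background is not None else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.4f}" for b, p in zip(BASES, bg)) + "\n\n")
        for i, motif in enumerate(motifs, start=1):
            name = consensus(motif.pwm)
            fh.write(f"MOTIF m{i} {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {motif.pwm.width} "
                f"nsites= {sum(1 for _, s in motif.site_scores if s is not None)} "
                f"E= {motif.evalue:.3g}\n"
            )
            for row in motif.pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
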