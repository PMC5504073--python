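"""Two-part CTCF motif machinery: discovery, exact p-values, and scanning.

The 16-bp core motif and the upstream (M2) motif are discovered de novo by
expectation-maximisation under a ZOOPS model (zero or one motif occurrence
per sequence) against a first-order Markov background.  Scanning assigns
each candidate position an exact p-value — the probability that a random
width-w sequence drawn from the order-0 background scores at least as high
— computed by dynamic programming over discretised log-odds column scores,
mirroring the semantics of standard PWM scanners.

Score discretisation rounds column scores down (conservative p-values);
scanning uses the same integer scores on both strands, so hit sets are
exactly strand-symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
_BASES = "ACGT"
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


class NoMotifError(RuntimeError):
    """Raised when motif discovery fails to find an informative motif."""


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN to 0..4 (N=4)."""
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(enc: np.ndarray) -> str:
    return "".join("ACGTN"[int(b)] for b in enc)


def revcomp(seq: str) -> str:
    return decode(_COMP[encode(seq)][::-1])


# ---------------------------------------------------------------------------
# Markov background
# ---------------------------------------------------------------------------


@dataclass
class MarkovBackground:
    """Order-0/1 Markov model of the scanning background.

    ``probs0`` is the marginal base distribution; for order 1, ``cond[i, j]``
    is P(next=j | previous=i).  A pseudocount is added to every count cell.
    """

    order: int
    probs0: np.ndarray
    cond: np.ndarray | None = None
    pseudo: float = 0.01
    source: str = ""

    def __post_init__(self) -> None:
        if abs(self.probs0.sum() - 1.0) > 1e-9 or np.any(self.probs0 < 0):
            raise ValueError("probs0 must be a distribution")
        if self.pseudo > 0 and np.any(self.probs0 <= 0):
            raise ValueError("probs0 must be strictly positive when pseudo > 0")
        if self.order == 1:
            if self.cond is None:
                raise ValueError("order-1 background requires conditional probabilities")
            if np.any(np.abs(self.cond.sum(axis=1) - 1.0) > 1e-9) or np.any(self.cond < 0):
                raise ValueError("each conditional distribution must sum to 1")


def train_markov_background(
    seqs: Sequence[str], order: int = 1, pseudo: float = 0.01, source: str = ""
) -> MarkovBackground:
    """Estimate a Markov background from sequences; N-containing windows skipped."""
    if order not in (0, 1):
        raise ValueError("only orders 0 and 1 are supported")
    if not seqs or all(not s for s in seqs):
        raise ValueError("no sequences to train background on")
    c0 = np.zeros(4)
    c1 = np.zeros((4, 4))
    for s in seqs:
        x = encode(s)
        valid = x < 4
        np.add.at(c0, x[valid], 1)
        if order == 1 and len(x) >= 2:
            ok = valid[:-1] & valid[1:]
            np.add.at(c1, (x[:-1][ok], x[1:][ok]), 1)
    if c0.sum() == 0:
        raise ValueError("sequences contain no ACGT bases")
    probs0 = (c0 + pseudo) / (c0.sum() + 4 * pseudo)
    cond = None
    if order == 1:
        rowsum = c1.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = (c1 + pseudo) / (rowsum + 4 * pseudo)
        # unseen predecessor states with pseudo=0: fall back to uniform
        cond = np.where((rowsum + 4 * pseudo) > 0, cond, 0.25)
    return MarkovBackground(order=order, probs0=probs0, cond=cond, pseudo=pseudo, source=source)


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------


@dataclass
class PWM:
    """Position weight matrix: per-column base probabilities (4 x width)."""

    probs: np.ndarray
    pseudo: float = 0.01

    def __post_init__(self) -> None:
        # width >= 4 is enforced at discovery time; tiny matrices are legal
        # containers (enumeration oracles use widths 1-5)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError("PWM must be a 4 x width matrix")
        if np.any(np.abs(self.probs.sum(axis=0) - 1.0) > 1e-9) or np.any(self.probs <= 0):
            raise ValueError("each PWM column must sum to 1 with positive entries")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=0))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (relative to uniform)."""
        p = self.probs
        return 2.0 + np.sum(p * np.log2(p), axis=0)

    def log_odds(self, background0: np.ndarray) -> np.ndarray:
        """Log2 odds vs an order-0 background, shape (4, width)."""
        return np.log2(self.probs / background0[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(probs=self.probs[::-1, ::-1].copy(), pseudo=self.pseudo)

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudo: float, background0: np.ndarray) -> "PWM":
        denom = counts.sum(axis=0) + pseudo
        probs = (counts + pseudo * background0[:, None]) / denom
        return cls(probs=probs, pseudo=pseudo)

    def write_meme(self, path, name: str = "motif", background0: np.ndarray | None = None) -> None:
        """Serialise in MEME minimal motif format."""
        bg = background0 if background0 is not None else np.full(4, 0.25)
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\n")
            fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.width}\n")
            for c in range(self.width):
                fh.write(" ".join(f"{self.probs[b, c]:.6f}" for b in range(4)) + "\n")


def read_meme(path) -> PWM:
    rows = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) != 4:
                    break
                rows.append([float(v) for v in parts])
    if not rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    probs = np.array(rows).T
    probs /= probs.sum(axis=0, keepdims=True)  # undo serialisation rounding
    return PWM(probs=probs)


# ---------------------------------------------------------------------------
# exact p-values by dynamic programming
# ---------------------------------------------------------------------------


class ScorePvalueTable:
    """Monotone map from PWM score to exact background p-value.

    Column log-odds are discretised to integers (floored, ``granularity``
    bins per column on average) and the distribution of the integer total
    score under the order-0 background is built by convolution; the p-value
    of a score is the suffix mass at its integer value.
    """

    def __init__(self, pwm: PWM, background0: np.ndarray, granularity: int = 1000):
        if granularity < 100:
            raise ValueError("granularity must be >= 100 bins per column")
        lo = pwm.log_odds(background0)
        w = pwm.width
        col_min = lo.min(axis=0)
        total_range = float((lo.max(axis=0) - col_min).sum())
        self.delta = total_range / (granularity * w) if total_range > 0 else 1.0
        self.offset = float(col_min.sum())
        self.int_scores = np.floor((lo - col_min[None, :]) / self.delta).astype(np.int64)
        self.width = w
        pmf = np.array([1.0])
        for c in range(w):
            shifts = self.int_scores[:, c]
            new = np.zeros(len(pmf) + int(shifts.max()))
            for b in range(4):
                new[shifts[b] : shifts[b] + len(pmf)] += background0[b] * pmf
            pmf = new
        sf = np.cumsum(pmf[::-1])[::-1]
        self.suffix = np.clip(sf, 0.0, 1.0)

    @property
    def max_int(self) -> int:
        return len(self.suffix) - 1

    def pvalue_from_int(self, k) -> np.ndarray:
        k = np.clip(np.asarray(k), 0, self.max_int)
        return self.suffix[k]

    def pvalue(self, score) -> np.ndarray:
        """p-value of a float score (floored onto the integer grid)."""
        k = np.floor((np.asarray(score, dtype=float) - self.offset) / self.delta).astype(np.int64)
        return self.pvalue_from_int(k)

    def rc_int_scores(self) -> np.ndarray:
        """Integer scores of the reverse-complement motif on the forward strand."""
        return self.int_scores[::-1, ::-1]


def score_pvalue_table(
    pwm: PWM, background0: np.ndarray, granularity: int = 1000
) -> ScorePvalueTable:
    return ScorePvalueTable(pwm, background0, granularity)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


@dataclass
class ScanWindow:
    """A sequence window to scan, anchored at genome coordinates.

    For oriented windows (upstream extensions of minus-strand core hits) the
    stored sequence is already reverse-complemented; ``start`` remains the
    forward-strand coordinate of the window's left edge.
    """

    peak_id: str
    chrom: str
    start: int
    seq: str


@dataclass
class MotifHit:
    peak_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float


def _window_int_scores(X: np.ndarray, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total integer score and validity mask for all windows of X (n, L)."""
    n, L = X.shape
    w = ints.shape[1]
    m = L - w + 1
    ints5 = np.vstack([ints, np.zeros((1, w), dtype=ints.dtype)])
    total = np.zeros((n, m), dtype=np.int64)
    n_count = np.zeros((n, m), dtype=np.int32)
    isn = (X == 4).astype(np.int32)
    for c in range(w):
        total += ints5[X[:, c : c + m], c]
        n_count += isn[:, c : c + m]
    return total, n_count == 0


def scan(
    windows: Sequence[ScanWindow],
    pwm: PWM,
    background0: np.ndarray,
    thresh_p: float,
    strands: str = "both",
    granularity: int = 1000,
    table: ScorePvalueTable | None = None,
) -> list[MotifHit]:
    """All positions with exact p-value <= thresh_p, on the requested strands.

    Minus-strand hits report forward-strand footprint coordinates.  Windows
    containing N at a candidate position skip that position.
    """
    if not (0 < thresh_p <= 1):
        raise ValueError("thresh_p must be in (0, 1]")
    if strands not in {"both", "forward"}:
        raise ValueError("strands must be 'both' or 'forward'")
    if table is None:
        table = ScorePvalueTable(pwm, background0, granularity)
    w = pwm.width
    hits: list[MotifHit] = []
    by_len: dict[int, list[ScanWindow]] = {}
    for win in windows:
        if len(win.seq) >= w:
            by_len.setdefault(len(win.seq), []).append(win)
    strand_ints = [("+", table.int_scores)]
    if strands == "both":
        strand_ints.append(("-", table.rc_int_scores()))
    for L, group in sorted(by_len.items()):
        X = np.vstack([encode(g.seq) for g in group])
        for strand, ints in strand_ints:
            total, valid = _window_int_scores(X, ints)
            pvals = table.pvalue_from_int(total)
            sel = valid & (pvals <= thresh_p)
            scores = total * table.delta + table.offset
            for i, j in zip(*np.nonzero(sel)):
                g = group[i]
                hits.append(
                    MotifHit(
                        peak_id=g.peak_id,
                        chrom=g.chrom,
                        start=g.start + int(j),
                        end=g.start + int(j) + w,
                        strand=strand,
                        score=float(scores[i, j]),
                        pvalue=float(pvals[i, j]),
                    )
                )
    hits.sort(key=lambda h: (h.peak_id, h.chrom, h.start, h.strand))
    return hits


def best_hit_per_peak(hits: Iterable[MotifHit]) -> dict[str, MotifHit]:
    """Lowest-p hit per peak; ties: higher score, leftmost start, then + strand."""
    best: dict[str, MotifHit] = {}
    for h in hits:
        cur = best.get(h.peak_id)
        if cur is None or _hit_order(h) < _hit_order(cur):
            best[h.peak_id] = h
    return best


def _hit_order(h: MotifHit):
    return (h.pvalue, -h.score, h.start, 0 if h.strand == "+" else 1)


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery
# ---------------------------------------------------------------------------


@dataclass
class EMResult:
    pwm: PWM
    gamma: float
    log_likelihood: float
    ll_trace: list[float]
    occurrence_posterior: np.ndarray
    start_word: str
    n_iter: int
    converged: bool
    significant: bool = True  # False when the no-motif model is preferred


class _Batch:
    """Equal-length sequence group with precomputed background log-probs."""

    def __init__(self, X: np.ndarray, idx: np.ndarray, width: int, bg: MarkovBackground,
                 strands: str):
        self.idx = idx
        n, L = X.shape
        self.m = L - width + 1
        self.strands = [X]
        if strands == "both":
            self.strands.append(_COMP[X][:, ::-1])
        self.bg_logp = [self._bg_window_logp(x, width, bg) for x in self.strands]
        self.valid = [np.isfinite(b) for b in self.bg_logp]
        self.n_valid = sum(v.sum(axis=1) for v in self.valid)

    @staticmethod
    def _bg_window_logp(X: np.ndarray, w: int, bg: MarkovBackground) -> np.ndarray:
        n, L = X.shape
        m = L - w + 1
        Xc = np.minimum(X, 3)
        lp0 = np.log(bg.probs0)[Xc]
        if bg.order == 1:
            pair = np.log(bg.cond)[Xc[:, :-1], Xc[:, 1:]]
        else:
            pair = lp0[:, 1:]
        cp = np.concatenate([np.zeros((n, 1)), np.cumsum(pair, axis=1)], axis=1)
        out = lp0[:, :m] + (cp[:, w - 1 :] - cp[:, : m])
        ncount = np.zeros((n, m), dtype=np.int32)
        isn = (X == 4).astype(np.int32)
        for c in range(w):
            ncount += isn[:, c : c + m]
        out[ncount > 0] = -np.inf
        return out

    def pwm_window_logp(self, log_probs: np.ndarray) -> list[np.ndarray]:
        w = log_probs.shape[1]
        lp5 = np.vstack([log_probs, np.zeros((1, w))])
        out = []
        for x, valid in zip(self.strands, self.valid):
            s = np.zeros((x.shape[0], self.m))
            for c in range(w):
                s += lp5[x[:, c : c + self.m], c]
            s[~valid] = -np.inf
            out.append(s)
        return out


def _seed_words(batches: list[_Batch], width: int, bg: MarkovBackground,
                n_starts: int) -> list[str]:
    """Most background-over-represented exact w-mers across all windows."""
    powers = 4 ** np.arange(width, dtype=np.int64)
    counts: dict[int, int] = {}
    total_windows = 0
    for b in batches:
        X = b.strands[0]
        m = b.m
        v = np.zeros((X.shape[0], m), dtype=np.int64)
        ncount = np.zeros((X.shape[0], m), dtype=np.int32)
        isn = (X == 4).astype(np.int32)
        for c in range(width):
            v += np.minimum(X[:, c : c + m], 3).astype(np.int64) * powers[c]
            ncount += isn[:, c : c + m]
        vals = v[ncount == 0]
        total_windows += vals.size
        uniq, cnt = np.unique(vals, return_counts=True)
        for u, k in zip(uniq, cnt):
            counts[int(u)] = counts.get(int(u), 0) + int(k)
    if not counts:
        raise NoMotifError("no N-free windows to seed motif discovery")
    words = np.array(sorted(counts), dtype=np.int64)
    cnt = np.array([counts[int(u)] for u in words], dtype=float)
    keep = cnt >= 5
    if keep.any():
        words, cnt = words[keep], cnt[keep]
    digits = (words[:, None] // powers[None, :]) % 4
    lp = np.log(bg.probs0)[digits[:, 0]]
    if bg.order == 1:
        lp += np.log(bg.cond)[digits[:, :-1], digits[:, 1:]].sum(axis=1)
    else:
        lp += np.log(bg.probs0)[digits[:, 1:]].sum(axis=1)
    # Poisson surprise: weight the log enrichment by the occurrence count so
    # abundant motif words beat rare high-ratio background words
    enrich = cnt * (np.log(cnt) - (np.log(total_windows) + lp))
    order = np.lexsort((words, -enrich))
    seeds = []
    for i in order[:n_starts]:
        seeds.append("".join(_BASES[d] for d in digits[i]))
    return seeds


def em_discover(
    seqs: Sequence[str],
    width: int,
    background: MarkovBackground,
    n_starts: int = 5,
    seed: int = 0,
    model: str = "ZOOPS",
    strands: str = "both",
    max_iter: int = 100,
    tol: float = 1e-6,
    pseudo: float = 0.01,
) -> EMResult:
    """Discover one motif by ZOOPS EM against the Markov background.

    Each sequence contributes zero or one occurrence; the E-step computes
    the posterior over occurrence positions (both strands by default) versus
    the background, the M-step re-estimates the PWM from expected counts.
    Restarts are seeded from the ``n_starts`` most background-over-represented
    exact words; the best final likelihood wins.  The log-likelihood
    (reported up to the constant all-background term) is non-decreasing
    across iterations.
    """
    if width < 4:
        raise ValueError("motif width must be >= 4")
    if model != "ZOOPS":
        raise ValueError("only the ZOOPS model is implemented")
    usable = [(i, s) for i, s in enumerate(seqs) if len(s) >= width]
    if not usable:
        raise ValueError("no sequence is at least as long as the motif width")
    if len(usable) < len(seqs):
        logger.warning("em_discover: dropped %d sequences shorter than width",
                       len(seqs) - len(usable))
    by_len: dict[int, list[tuple[int, str]]] = {}
    for i, s in usable:
        by_len.setdefault(len(s), []).append((i, s))
    batches = []
    for L in sorted(by_len):
        grp = by_len[L]
        X = np.vstack([encode(s) for _, s in grp])
        idx = np.array([i for i, _ in grp])
        batches.append(_Batch(X, idx, width, background, strands))

    rng = np.random.default_rng(seed)
    seeds = _seed_words(batches, width, background, n_starts)
    best: EMResult | None = None
    for word in seeds:
        res = _run_em(batches, word, width, background, len(seqs), max_iter, tol, pseudo, rng)
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    assert best is not None
    # Model selection: a ZOOPS fit can sharpen onto a handful of background
    # windows, so accept the motif only if its likelihood gain over the
    # no-occurrence model survives a BIC penalty (3w PWM parameters + gamma).
    # Otherwise report the honest no-motif answer: a background-flat PWM.
    n_params = 3 * width + 1
    if 2.0 * best.log_likelihood < n_params * np.log(max(len(usable), 2)):
        best.significant = False
        best.pwm = PWM(probs=np.tile(background.probs0[:, None], (1, width)), pseudo=pseudo)
        best.gamma = 0.0
    return best


def _run_em(batches, start_word, width, bg, n_seqs, max_iter, tol, pseudo, rng) -> EMResult:
    probs = np.full((4, width), 0.1)
    for c, ch in enumerate(start_word):
        probs[:, c] = 0.1
        probs[_BASES.index(ch), c] = 0.7
    pwm = PWM(probs=probs, pseudo=pseudo)
    gamma = 0.5
    trace: list[float] = []
    converged = False
    it = 0
    Q_full = np.zeros(n_seqs)
    for it in range(1, max_iter + 1):
        counts = np.zeros((4, width))
        ll = 0.0
        q_sum = 0.0
        n_total = 0
        lp = np.log(pwm.probs)
        for b in batches:
            pwm_lp = b.pwm_window_logp(lp)
            # likelihood ratio per window, linear domain (scores are modest)
            with np.errstate(invalid="ignore"):
                R = [np.exp(np.where(np.isfinite(p) & np.isfinite(g), p - g, -np.inf))
                     for p, g in zip(pwm_lp, b.bg_logp)]
            m_i = np.maximum(b.n_valid, 1)
            sumR = sum(r.sum(axis=1) for r in R)
            denom = (1.0 - gamma) + (gamma / m_i) * sumR
            ll += float(np.log(denom).sum())
            Q = (gamma / m_i) * sumR / denom
            Q_full[b.idx] = Q
            q_sum += float(Q.sum())
            n_total += len(m_i)
            for x, r in zip(b.strands, R):
                z = (gamma / m_i)[:, None] * r / denom[:, None]
                m = b.m
                for c in range(width):
                    counts[:, c] += np.bincount(
                        x[:, c : c + m].ravel(), weights=z.ravel(), minlength=5
                    )[:4]
        trace.append(ll)
        if len(trace) >= 2:
            delta = trace[-1] - trace[-2]
            if delta < -1e-6 * (abs(ll) + 1.0):
                logger.warning("EM log-likelihood decreased by %g", -delta)
            if abs(delta) < tol * (abs(ll) + 1.0):
                converged = True
                break
        pwm = PWM.from_counts(counts, pseudo, bg.probs0)
        gamma = min(max(q_sum / n_total, 1e-6), 1.0 - 1e-6)
    return EMResult(
        pwm=pwm,
        gamma=gamma,
        log_likelihood=trace[-1],
        ll_trace=trace,
        occurrence_posterior=Q_full,
        start_word=start_word,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# two-part pipeline
# ---------------------------------------------------------------------------


@dataclass
class TwoPartConfig:
    top_n: int = 2000
    core_width: int = 16
    upstream_width: int = 10
    core_thresh: float = 1e-4
    upstream_thresh: float = 1e-3
    ext: int = 20
    flank: int = 100
    pseudo: float = 0.01
    n_starts: int = 3
    seed: int = 0
    min_core_ic: float = 0.5  # bits; max column IC below this means "no motif"
    granularity: int = 1000


@dataclass
class TwoPartResult:
    core_pwm: PWM
    upstream_pwm: PWM
    background: MarkovBackground
    best_core_hit: dict[str, MotifHit]
    upstream_flag: dict[str, bool]
    core_em: EMResult
    upstream_em: EMResult | None
    n_peaks: int


def peak_scan_windows(peaks, genome, flank: int) -> list[ScanWindow]:
    """Summit +/- flank sequence windows; windows clipped at contig edges are
    dropped (with a warning) to keep window lengths homogeneous."""
    out = []
    dropped = 0
    for p in peaks:
        lo, hi = p.summit - flank, p.summit + flank + 1
        L = len(genome.records[p.chrom])
        if lo < 0 or hi > L:
            dropped += 1
            continue
        out.append(ScanWindow(peak_id=p.name, chrom=p.chrom, start=lo,
                              seq=genome.fetch(p.chrom, lo, hi)))
    if dropped:
        logger.warning("peak_scan_windows: dropped %d edge-clipped windows", dropped)
    return out


def upstream_windows(
    core_hits: Iterable[MotifHit], genome, ext: int = 20
) -> list[ScanWindow]:
    """The ext-bp window 5' of each core hit, on the hit's own strand.

    For plus-strand hits this is the ext bp left of the footprint; for
    minus-strand hits the ext bp right of it, reverse-complemented, so the
    returned sequence always reads 5'->3' on the motif strand.  Windows
    truncated at contig edges are dropped with a warning.
    """
    out = []
    dropped = 0
    for h in core_hits:
        L = len(genome.records[h.chrom])
        if h.strand == "+":
            lo, hi = h.start - ext, h.start
            if lo < 0:
                dropped += 1
                continue
            seq = genome.fetch(h.chrom, lo, hi)
        else:
            lo, hi = h.end, h.end + ext
            if hi > L:
                dropped += 1
                continue
            seq = revcomp(genome.fetch(h.chrom, lo, hi))
        out.append(ScanWindow(peak_id=h.peak_id, chrom=h.chrom, start=lo, seq=seq))
    if dropped:
        logger.warning("upstream_windows: dropped %d contig-edge windows", dropped)
    return out


def two_part_pipeline(consensus_peaks, genome, cfg: TwoPartConfig | None = None) -> TwoPartResult:
    """Discover the core and upstream motifs and flag their presence per peak.

    Training uses the top-N peaks by fold enrichment (summit +/- flank);
    scanning covers all peak windows at the core threshold, then the 20-bp
    5' extensions of the best core hit per peak at the upstream threshold,
    restricted to the core hit's strand.
    """
    from ctcf_landscape.peaks import ConsensusPeakSet, top_peaks_by_fe

    cfg = cfg or TwoPartConfig()
    peaks = consensus_peaks.peaks if isinstance(consensus_peaks, ConsensusPeakSet) else list(consensus_peaks)
    all_windows = peak_scan_windows(peaks, genome, cfg.flank)
    top = top_peaks_by_fe(peaks, cfg.top_n)
    top_ids = {p.name for p in top}
    train_seqs = [w.seq for w in all_windows if w.peak_id in top_ids]
    bg = train_markov_background(train_seqs, order=1, pseudo=cfg.pseudo,
                                 source=f"top {len(train_seqs)} peak windows (summit +/- {cfg.flank} bp)")
    core_em = em_discover(train_seqs, cfg.core_width, bg, n_starts=cfg.n_starts, seed=cfg.seed,
                          pseudo=cfg.pseudo)
    if core_em.pwm.information_content().max() < cfg.min_core_ic:
        raise NoMotifError(
            f"no core motif: max column information "
            f"{core_em.pwm.information_content().max():.2f} bits < {cfg.min_core_ic}"
        )
    bg0 = bg.probs0
    core_table = ScorePvalueTable(core_em.pwm, bg0, cfg.granularity)
    core_hits = scan(all_windows, core_em.pwm, bg0, cfg.core_thresh, table=core_table)
    best = best_hit_per_peak(core_hits)

    # A de-novo core PWM is orientation-ambiguous (a motif and its reverse
    # complement explain the data equally well), but the two-part geometry is
    # not: the upstream partner sits 5' of the core on the core's strand.
    # Fix the orientation by running the upstream stage under both and
    # keeping the one whose upstream motif explains its windows better.
    core_pwm = core_em.pwm
    candidates = []
    for flipped in (False, True):
        cand_best = (
            best
            if not flipped
            else {
                k: MotifHit(h.peak_id, h.chrom, h.start, h.end,
                            "-" if h.strand == "+" else "+", h.score, h.pvalue)
                for k, h in best.items()
            }
        )
        up_wins = upstream_windows(cand_best.values(), genome, cfg.ext)
        up_em = None
        if up_wins:
            up_em = em_discover([w.seq for w in up_wins], cfg.upstream_width, bg,
                                n_starts=cfg.n_starts, seed=cfg.seed, strands="forward",
                                pseudo=cfg.pseudo)
        ll = up_em.log_likelihood if up_em is not None else -np.inf
        candidates.append((ll, flipped, cand_best, up_wins, up_em))
    ll, flipped, best, up_wins, upstream_em = max(candidates, key=lambda t: t[0])
    if flipped:
        core_pwm = core_pwm.reverse_complement()

    up_flags: dict[str, bool] = {p.name: False for p in peaks}
    if upstream_em is not None:
        up_pwm = upstream_em.pwm
        up_hits = scan(up_wins, up_pwm, bg0, cfg.upstream_thresh, strands="forward")
        for h in up_hits:
            up_flags[h.peak_id] = True
    else:
        up_pwm = PWM(probs=np.full((4, cfg.upstream_width), 0.25), pseudo=cfg.pseudo)
    return TwoPartResult(
        core_pwm=core_pwm,
        upstream_pwm=up_pwm,
        background=bg,
        best_core_hit=best,
        upstream_flag=up_flags,
        core_em=core_em,
        upstream_em=upstream_em,
        n_peaks=len(peaks),
    )


def fe_bin_proportions(peaks, two_part: TwoPartResult, bin_edges: Sequence[float]):
    """Per fold-enrichment bin: peak count, core-motif fraction, and
    core+upstream fraction (always <= core fraction)."""
    import pandas as pd

    fes = [p.fold_enrichment for p in peaks]
    if fes and (min(fes) < bin_edges[0] or max(fes) >= bin_edges[-1]):
        raise ValueError("bin_edges must cover all fold-enrichment values")
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = [p for p in peaks if lo <= p.fold_enrichment < hi]
        n = len(sel)
        n_core = sum(1 for p in sel if p.name in two_part.best_core_hit)
        n_both = sum(
            1
            for p in sel
            if p.name in two_part.best_core_hit and two_part.upstream_flag.get(p.name, False)
        )
        rows.append(
            {
                "fe_lo": lo,
                "fe_hi": hi,
                "n_peaks": n,
                "frac_core": n_core / n if n else 0.0,
                "frac_core_plus_upstream": n_both / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
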