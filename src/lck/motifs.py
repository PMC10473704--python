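"""Position weight matrices, log-odds scanning and motif-presence summaries.

Scores are in bits (log2-odds summed over positions). Both strands are
always scanned; a hit's position convention package-wide is
center-to-center: ``offset`` is the hit midpoint minus the peak summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import Peak, ValidationError, warn

ALPHABET = "ACGT"
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; any ambiguity code -> 4 (scores as background)."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


@dataclass
class PWM:
    """4 x L column-stochastic probability matrix over (A, C, G, T)."""

    probs: np.ndarray
    name: str = "pwm"
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValidationError("PWM must have 4 rows (A, C, G, T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError("PWM columns must each sum to 1")
        if np.any(self.probs < 0):
            raise ValidationError("PWM entries must be >= 0")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValidationError("background must be a 4-vector summing to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds; row 4 is the zero-contribution row for N.
        Zero probabilities (pseudocount 0) map to -inf: such a base can
        never appear in a hit."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[:, None])
        return np.vstack([lo, np.zeros((1, self.length))])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))

    def consensus_score(self) -> float:
        return float(np.log2(self.probs.max(axis=0) / 0.25).sum()) if np.allclose(
            self.background, 0.25
        ) else float(
            self.log_odds[np.argmax(self.probs, axis=0), np.arange(self.length)].sum()
        )

    def reverse_complement(self) -> "PWM":
        probs = self.probs[[3, 2, 1, 0], ::-1]
        bg = self.background[[3, 2, 1, 0]]
        return PWM(probs=probs, name=self.name + "_rc", background=bg,
                   pseudocount=self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif match. ``start`` is the hit start in scan coordinates;
    ``offset`` (when peak-anchored) is hit midpoint minus peak summit."""

    start: int
    strand: str
    score: float
    peak_id: str | None = None
    offset: int | None = None


def build_pwm(aligned_sites: list[str], pseudocount: float = 0.5, name: str = "pwm",
              background: np.ndarray | None = None) -> PWM:
    """Estimate a PWM from >= 2 equal-length ACGT sites:
    p[b, j] = (count_bj + pseudocount) / (N + 4 * pseudocount)."""
    if len(aligned_sites) < 2:
        raise ValidationError("need >= 2 aligned sites")
    L = len(aligned_sites[0])
    if any(len(s) != L for s in aligned_sites):
        raise ValidationError("aligned sites must have equal length")
    counts = np.zeros((4, L))
    for s in aligned_sites:
        enc = encode(s)
        bad = np.flatnonzero(enc == 4)
        if bad.size:
            raise ValidationError(
                f"non-ACGT character {s[bad[0]]!r} at position {int(bad[0])} in {s!r}"
            )
        counts[enc, np.arange(L)] += 1
    probs = (counts + pseudocount) / (len(aligned_sites) + 4 * pseudocount)
    kwargs = {} if background is None else {"background": background}
    return PWM(probs=probs, name=name, pseudocount=pseudocount, **kwargs)


def _window_scores(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every length-L window of an encoded sequence."""
    L = log_odds.shape[1]
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.arange(n)[:, None] + np.arange(L)[None, :]
    return log_odds[enc[idx], np.arange(L)[None, :]].sum(axis=1)


def scan(pwm: PWM, seq: str, min_score: float) -> list[MotifHit]:
    """Scan both strands; return hits scoring >= min_score, sorted by score
    descending, ties by position ascending then '+' strand first.
    Coincident equal-score +/- hits (palindromes) collapse to '+'."""
    if len(seq) < pwm.length:
        raise ValidationError("sequence shorter than the motif")
    enc = encode(seq)
    fwd = _window_scores(enc, pwm.log_odds)
    rev = _window_scores(enc, pwm.reverse_complement().log_odds)
    hits: dict[tuple[int, str], float] = {}
    for pos in np.flatnonzero(fwd >= min_score):
        hits[(int(pos), "+")] = float(fwd[pos])
    for pos in np.flatnonzero(rev >= min_score):
        key = (int(pos), "-")
        plus = hits.get((int(pos), "+"))
        if plus is not None and np.isclose(plus, rev[pos]):
            continue  # palindromic duplicate collapses to +
        hits[key] = float(rev[pos])
    out = [MotifHit(start=p, strand=s, score=sc) for (p, s), sc in hits.items()]
    out.sort(key=lambda h: (-h.score, h.start, h.strand))
    return out


def default_min_score(pwm: PWM) -> float:
    """Package default hit threshold: 0.8 x the consensus score."""
    return 0.8 * pwm.consensus_score()


def best_hit_near_center(
    pwm: PWM,
    peak: Peak,
    genome: dict[str, str],
    window: int = 50,
    min_score: float | None = None,
) -> MotifHit | None:
    """Best-scoring hit whose midpoint lies within +/- window of the peak
    summit; ties broken by smaller |offset| then leftmost. None if no hit
    passes ``min_score`` (default 0.8 x consensus score)."""
    if min_score is None:
        min_score = default_min_score(pwm)
    L = pwm.length
    seq = genome[peak.chrom]
    summit = peak.summit
    lo = summit - window - L
    hi = summit + window + L
    if lo < 0 or hi > len(seq):
        warn(f"scan window for {peak.name} truncated at chromosome boundary")
        lo, hi = max(lo, 0), min(hi, len(seq))
    region = seq[lo:hi]
    if len(region) < L:
        return None
    best = None
    for h in scan(pwm, region, min_score):
        start = lo + h.start
        center = start + L // 2
        offset = center - summit
        if abs(offset) > window:
            continue
        key = (-h.score, abs(offset), start)
        if best is None or key < best[0]:
            best = (key, MotifHit(start=start, strand=h.strand, score=h.score,
                                  peak_id=peak.name, offset=offset))
    return None if best is None else best[1]


def motif_presence(
    peak_subsets: dict[str, list[Peak]],
    pwm: PWM,
    genome: dict[str, str],
    window: int = 50,
    min_score: float | None = None,
) -> pd.DataFrame:
    """Fraction of peaks per subset with a best hit near the summit, plus the
    mean best-hit score (the "motif stringency" readout). Subsets must be
    disjoint; empty subsets report NA fractions."""
    seen: set[str] = set()
    for label, subset in peak_subsets.items():
        names = {p.name for p in subset}
        if names & seen:
            raise ValidationError("peak subsets must be disjoint")
        seen |= names
    rows = []
    for label, subset in peak_subsets.items():
        if not subset:
            rows.append({"subset": label, "n_peaks": 0, "n_with_motif": 0,
                         "fraction_with_motif": np.nan, "mean_best_score": np.nan})
            continue
        scores = []
        for p in subset:
            h = best_hit_near_center(pwm, p, genome, window=window, min_score=min_score)
            if h is not None:
                scores.append(h.score)
        rows.append(
            {
                "subset": label,
                "n_peaks": len(subset),
                "n_with_motif": len(scores),
                "fraction_with_motif": len(scores) / len(subset),
                "mean_best_score": float(np.mean(scores)) if scores else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PWM text formats


def write_meme(pwms: list[PWM], path) -> None:
    """MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.probs.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms = []
    name, rows, background = None, [], np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if line.startswith("Background letter frequencies"):
            toks = next(lines).split()
            background = np.array([float(toks[i]) for i in (1, 3, 5, 7)])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            rows = []
        elif line.startswith("letter-probability"):
            continue
        elif name is not None and line.strip():
            rows.append([float(v) for v in line.split()])
        elif name is not None and rows:
            pwms.append(PWM(probs=np.array(rows).T, name=name, background=background))
            name, rows = None, []
    if name is not None and rows:
        pwms.append(PWM(probs=np.array(rows).T, name=name, background=background))
    return pwms


def read_jaspar_pfm(path, pseudocount: float = 0.5) -> PWM:
    """JASPAR-style PFM: a '>name' header then 4 count rows (A, C, G, T)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    name = lines[0][1:].split()[0] if lines[0].startswith(">") else "pfm"
    rows = [ln for ln in lines if not ln.startswith(">")]
    counts = np.array(
        [[float(v) for v in row.strip("ACGT []").split()] for row in rows[:4]]
    )
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    return PWM(probs=probs, name=name, pseudocount=pseudocount)
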