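"""Ungapped motif discovery by ZOOPS expectation–maximization.

A MEME-style surrogate: for each candidate width the EM is started from the
top-scoring substring seeds, and the best converged model is kept by an
information-content-per-column x expected-site-count score.  Found sites are
masked before searching for the next motif.  ZOOPS means each sequence
contributes zero or one site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .seqio import SequenceRecord

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

PSEUDOCOUNT = 0.1
CONVERGENCE_TOL = 1e-4
MAX_ITER = 100
N_SEEDS = 5


@dataclass
class Background:
    """0-order letter frequencies (pseudocounted, strictly positive)."""

    alphabet: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.alphabet):
            raise ValueError("frequency/alphabet length mismatch")
        if np.any(self.frequencies <= 0):
            raise ValueError("background frequencies must be > 0")
        self.frequencies = self.frequencies / self.frequencies.sum()

    @classmethod
    def from_counts(cls, counts: np.ndarray, alphabet: str) -> "Background":
        return cls(alphabet, counts + PSEUDOCOUNT)


@dataclass
class PWM:
    """Per-position letter probabilities of an ungapped motif."""

    matrix: np.ndarray  # (width, alphabet)
    alphabet: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(self.alphabet[i] for i in self.matrix.argmax(axis=1))

    def information_content(self, background: Background) -> float:
        """Total relative-entropy IC in bits, summed over columns."""
        p = self.matrix
        return float(np.sum(p * np.log2(p / background.frequencies[None, :])))


@dataclass
class MotifModel:
    pwm: PWM
    sites: list[tuple[str, int, str]]  # (record id, offset, strand)
    information_content: float
    score: float
    consensus: str = field(default="")

    def __post_init__(self) -> None:
        if not self.consensus:
            self.consensus = self.pwm.consensus()

    def to_meme_text(self, background: Background) -> str:
        lines = ["MEME version 4", "",
                 f"ALPHABET= {background.alphabet}", "",
                 "Background letter frequencies",
                 " ".join(f"{c} {f:.4f}" for c, f in
                          zip(background.alphabet, background.frequencies)),
                 "",
                 f"MOTIF {self.consensus}",
                 f"letter-probability matrix: alength= "
                 f"{len(background.alphabet)} w= {self.pwm.width} "
                 f"nsites= {len(self.sites)}"]
        for row in self.pwm.matrix:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def score_site(pwm: PWM, background: Background, subsequence: str) -> float:
    """Log-odds score (bits) of one subsequence: sum log2(p_pos(c)/bg(c))."""
    if len(subsequence) != pwm.width:
        raise ValueError(
            f"subsequence length {len(subsequence)} != PWM width {pwm.width}")
    idx = [pwm.alphabet.index(c) for c in subsequence.upper()]
    return float(sum(
        np.log2(pwm.matrix[k, a] / background.frequencies[a])
        for k, a in enumerate(idx)))


# ---------------------------------------------------------------------------
# internal machinery


def _encode(records: list[SequenceRecord], alphabet: str) -> list[np.ndarray]:
    lut = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    return [lut[np.frombuffer(r.residues.encode(), dtype=np.uint8)]
            for r in records]


def _windows(enc: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """(windows, valid) — valid excludes windows touching masked positions."""
    if len(enc) < w:
        return np.empty((0, w), dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    return win, (win >= 0).all(axis=1)


class _ZoopsEM:
    """One EM fit at fixed width from one seed."""

    def __init__(self, windows: list[np.ndarray], valid: list[np.ndarray],
                 background: Background, w: int):
        self.windows = windows
        self.valid = valid
        self.bg = background
        self.w = w
        self.A = len(background.alphabet)
        logbg = np.log(background.frequencies)
        self.bg_scores = []  # log P(window | bg) for valid windows
        for win, ok in zip(windows, valid):
            s = np.full(len(ok), -np.inf)
            if ok.any():
                s[ok] = logbg[win[ok]].sum(axis=1)
            self.bg_scores.append(s)

    def pwm_from_seed(self, seed: np.ndarray, match_p: float = 0.7) -> np.ndarray:
        m = np.full((self.w, self.A), (1 - match_p) / (self.A - 1))
        m[np.arange(self.w), seed] = match_p
        return m

    def run(self, pwm0: np.ndarray, gamma0: float = 0.5
            ) -> tuple[np.ndarray, float, float, list[float]]:
        pwm = pwm0.copy()
        gamma = gamma0
        history: list[float] = []
        prev_ll = -np.inf
        for _ in range(MAX_ITER):
            logpwm = np.log(pwm)
            counts = np.full((self.w, self.A), PSEUDOCOUNT)
            gamma_num = 0.0
            ll = 0.0
            zs = []
            for win, ok, bg_s in zip(self.windows, self.valid, self.bg_scores):
                m = int(ok.sum())
                if m == 0:
                    zs.append(None)
                    continue
                site_s = logpwm[np.arange(self.w)[None, :],
                                win[ok]].sum(axis=1)
                # log joint for "site at j" vs "no site"; the background
                # probability of the off-site positions is a common factor,
                # so ll below is the ZOOPS log-likelihood up to a constant
                log_site = np.log(gamma / m) + site_s - bg_s[ok]
                terms = np.concatenate(([np.log1p(-gamma)], log_site))
                norm = logsumexp(terms)
                ll += norm
                z = np.zeros(len(ok))
                z[ok] = np.exp(log_site - norm)
                zs.append(z)
                gamma_num += z.sum()
                np.add.at(counts, (np.arange(self.w)[None, :], win[ok]),
                          z[ok][:, None])
            pwm = counts / counts.sum(axis=1, keepdims=True)
            n_eff = sum(1 for z in zs if z is not None)
            gamma = min(max(gamma_num / max(n_eff, 1), 1e-6), 1 - 1e-6)
            history.append(ll)
            if abs(ll - prev_ll) < CONVERGENCE_TOL:
                break
            prev_ll = ll
        return pwm, gamma, history[-1], history


def _seed_candidates(windows: list[np.ndarray], valid: list[np.ndarray],
                     rng: np.random.Generator, n_candidates: int = 30
                     ) -> list[np.ndarray]:
    """Sample substrings and keep the best by a consensus-match heuristic."""
    pool = []
    for win, ok in zip(windows, valid):
        idx = np.flatnonzero(ok)
        if len(idx):
            take = rng.choice(idx, size=min(4, len(idx)), replace=False)
            pool.extend(win[t] for t in take)
    if not pool:
        return []
    if len(pool) > n_candidates:
        pick = rng.choice(len(pool), size=n_candidates, replace=False)
        pool = [pool[i] for i in sorted(pick)]
    scored = []
    for cand in pool:
        total = 0
        for win, ok in zip(windows, valid):
            if ok.any():
                total += int((win[ok] == cand).sum(axis=1).max())
        scored.append((total, tuple(cand)))
    scored.sort(key=lambda t: (-t[0], t[1]))
    seen, out = set(), []
    for _, cand in scored:
        if cand not in seen:
            seen.add(cand)
            out.append(np.array(cand))
        if len(out) == N_SEEDS:
            break
    return out


def discover_motifs(records: list[SequenceRecord], nmotifs: int = 6,
                    wmin: int = 6, wmax: int = 50, seed: int = 0,
                    alphabet: str | None = None) -> list[MotifModel]:
    """Find up to `nmotifs` ungapped motifs by seeded ZOOPS EM.

    Candidate widths wmin..wmax are scanned in steps of 2; for each width EM
    runs from the top-5 substring seeds and the best converged model (by
    IC-per-column x expected-site-count) is kept.  Sites of each accepted
    motif are masked before the next round.  Deterministic for a fixed seed.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 records")
    if alphabet is None:
        letters = set("".join(r.residues.upper() for r in records))
        alphabet = DNA_ALPHABET if letters <= set("ACGTN") else PROTEIN_ALPHABET
    if all(len(r.residues) < wmin for r in records):
        raise ValueError(f"all records shorter than wmin={wmin}")

    encoded = _encode(records, alphabet)
    counts = np.zeros(len(alphabet))
    for e in encoded:
        good = e[e >= 0]
        counts += np.bincount(good, minlength=len(alphabet))
    background = Background.from_counts(counts, alphabet)

    rng = np.random.default_rng(seed)
    models: list[MotifModel] = []
    for _ in range(nmotifs):
        best: tuple[float, MotifModel] | None = None
        for w in range(wmin, wmax + 1, 2):
            wins, valids = [], []
            any_valid = False
            for e in encoded:
                win, ok = _windows(e, w)
                wins.append(win)
                valids.append(ok)
                any_valid = any_valid or bool(ok.any())
            if not any_valid:
                continue
            em = _ZoopsEM(wins, valids, background, w)
            for cand in _seed_candidates(wins, valids, rng):
                pwm_m, gamma, _, _ = em.run(em.pwm_from_seed(cand))
                pwm = PWM(pwm_m, alphabet)
                ic = pwm.information_content(background)
                exp_sites = gamma * len(records)
                score = (ic / w) * exp_sites
                if best is None or score > best[0]:
                    sites = _map_sites(records, encoded, pwm_m, background, w)
                    model = MotifModel(pwm, sites, ic, score)
                    best = (score, model)
        if best is None:
            break
        best = _refine_by_shift(best, records, encoded, background)
        model = best[1]
        models.append(model)
        # mask accepted sites before the next motif
        id_to_idx = {r.id: i for i, r in enumerate(records)}
        for rec_id, offset, _ in model.sites:
            i = id_to_idx[rec_id]
            encoded[i][offset:offset + model.pwm.width] = -1
    return models


def _refine_by_shift(best, records, encoded, background):
    """Escape phase-shifted optima: restart EM from site windows shifted by
    a few positions either way and keep the best-scoring model."""
    score0, model = best
    w = model.pwm.width
    wins, valids = zip(*(_windows(e, w) for e in encoded))
    em = _ZoopsEM(list(wins), list(valids), background, w)
    id_to_idx = {r.id: i for i, r in enumerate(records)}
    for _ in range(4):  # hill-climb over shifts until no improvement
        improved = None
        for delta in (-2, -1, 1, 2):
            counts = np.full((w, len(background.alphabet)), PSEUDOCOUNT)
            n_win = 0
            for rec_id, off, _ in model.sites:
                i = id_to_idx[rec_id]
                j = off + delta
                win, ok = wins[i], valids[i]
                if 0 <= j < len(ok) and ok[j]:
                    counts[np.arange(w), win[j]] += 1.0
                    n_win += 1
            if n_win < 2:
                continue
            pwm0 = counts / counts.sum(axis=1, keepdims=True)
            pwm_m, gamma, _, _ = em.run(pwm0)
            pwm = PWM(pwm_m, background.alphabet)
            ic = pwm.information_content(background)
            score = (ic / w) * gamma * len(records)
            if score > score0:
                sites = _map_sites(records, encoded, pwm_m, background, w)
                improved = (score, MotifModel(pwm, sites, ic, score))
                score0 = score
        if improved is None:
            break
        model = improved[1]
    return (score0, model)


def _map_sites(records, encoded, pwm_m, background, w
               ) -> list[tuple[str, int, str]]:
    """Best site per sequence (ZOOPS), kept when it beats the background."""
    logodds = np.log2(pwm_m / background.frequencies[None, :])
    sites = []
    for rec, e in zip(records, encoded):
        win, ok = _windows(e, w)
        if not ok.any():
            continue
        s = np.full(len(ok), -np.inf)
        s[ok] = logodds[np.arange(w)[None, :], win[ok]].sum(axis=1)
        j = int(np.argmax(s))
        if s[j] > 0:
            sites.append((rec.id, j, "+"))
    return sites


def sites_tsv(models: list[MotifModel]) -> str:
    lines = ["motif\trecord\toffset\tstrand"]
    for i, m in enumerate(models, 1):
        for rec, off, strand in m.sites:
            lines.append(f"{i}:{m.consensus}\t{rec}\t{off}\t{strand}")
    return "\n".join(lines) + "\n"
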