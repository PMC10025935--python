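"""Basecall-error model: a first-order chain over alignment event types.

Events (match, mismatch, insertion, deletion) are extracted as maximal runs
by walking alignment CIGAR strings.  The model keeps the empirical run-length
distribution of each event type and the transition frequencies between
consecutive runs (Laplace-smoothed); simulation alternates event runs sampled
from the chain until the template sequence is consumed.  Per-event Phred
quality histograms are learned when FASTQ input is available, enabling
optional quality-score simulation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ErrorModel", "fit_error_model", "introduce_errors", "assign_qualities", "replay_log"]

STATES = ("match", "mismatch", "insertion", "deletion")
_SIDX = {s: i for i, s in enumerate(STATES)}
_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_OP_STATE = {"=": "match", "M": "match", "X": "mismatch", "I": "insertion", "D": "deletion"}
_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_POOL = 8192


def _rle_merge(runs: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for state, ln in runs:
        if out and out[-1][0] == state:
            out[-1] = (state, out[-1][1] + ln)
        else:
            out.append((state, ln))
    return out


def cigar_runs(cigar: str) -> list[tuple[str, int]]:
    """Maximal (event, length) runs from a CIGAR string; clips are ignored and
    M is treated as match (mismatches are only visible with =/X CIGARs)."""
    runs = []
    pos = 0
    for m in _CIG_RE.finditer(cigar):
        pos = m.end()
        ln, op = int(m.group(1)), m.group(2)
        state = _OP_STATE.get(op)
        if state is not None:
            runs.append((state, ln))
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return _rle_merge(runs)


@dataclass
class ErrorModel:
    """Event-chain error model: transitions, run lengths, base choices, qualities."""

    transitions: np.ndarray  # 4x4 row-stochastic, zero diagonal
    run_lengths: dict[str, tuple[np.ndarray, np.ndarray]]  # state -> (values, probs)
    base_composition: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # ACGT frequencies for insertions/junk
    quality_hists: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.transitions.shape != (4, 4):
            raise ValueError("transitions must be 4x4")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        for st, (vals, probs) in self.run_lengths.items():
            if (np.asarray(vals) < 1).any():
                raise ValueError(f"{st}: run lengths must be >= 1")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        """A degenerate model producing a single full-length match run."""
        trans = np.full((4, 4), 1 / 3)
        np.fill_diagonal(trans, 0.0)
        runs = {st: (np.array([1]), np.array([1.0])) for st in STATES}
        runs["match"] = (np.array([10**9]), np.array([1.0]))
        return cls(transitions=trans, run_lengths=runs)

    def mean_run(self, state: str) -> float:
        vals, probs = self.run_lengths[state]
        return float((vals * probs).sum())

    def stationary_rates(self) -> dict[str, float]:
        """Expected per-template-base event rates implied by the chain.

        Stationary run frequencies are the leading left eigenvector of the
        transition matrix; rates are expected event bases divided by expected
        template bases (match + mismatch + deletion) per run cycle.
        """
        w, v = np.linalg.eig(self.transitions.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        exp_bases = {st: pi[_SIDX[st]] * self.mean_run(st) for st in STATES}
        template = exp_bases["match"] + exp_bases["mismatch"] + exp_bases["deletion"]
        return {st: exp_bases[st] / template for st in ("mismatch", "insertion", "deletion")}


def fit_error_model(
    alignments: Mapping[str, Sequence],
    reads: Mapping[str, object] | None = None,
    laplace: float = 1.0,
) -> ErrorModel:
    """Fit the event chain from primary alignments carrying CIGAR strings.

    When *reads* (with qualities) are supplied, per-event quality histograms
    and the base composition are learned as well.
    """
    trans_counts = np.zeros((4, 4))
    run_obs: dict[str, list[int]] = {st: [] for st in STATES}
    qual_obs: dict[str, list[int]] = {st: [] for st in STATES}
    base_counts = np.zeros(4)
    n_cigars = 0
    for read_id, subs in alignments.items():
        for sub in subs:
            if sub.cigar is None or not sub.is_primary:
                continue
            runs = cigar_runs(sub.cigar)
            if not runs:
                continue
            n_cigars += 1
            for st, ln in runs:
                run_obs[st].append(ln)
            for (a, _), (b, _) in zip(runs, runs[1:]):
                trans_counts[_SIDX[a], _SIDX[b]] += 1
            rec = None if reads is None else reads.get(read_id)
            if rec is not None and getattr(rec, "qualities", None) is not None:
                qpos = 0
                for m in _CIG_RE.finditer(sub.cigar):
                    ln, op = int(m.group(1)), m.group(2)
                    if op in "SH":
                        qpos += ln if op == "S" else 0
                        continue
                    st = _OP_STATE.get(op)
                    if st is None:
                        continue
                    if st in ("match", "mismatch", "insertion"):
                        qual_obs[st].extend(rec.qualities[qpos : qpos + ln])
                        qpos += ln
            if rec is not None:
                for i, b in enumerate("ACGT"):
                    base_counts[i] += rec.sequence.count(b)
    if n_cigars == 0:
        raise ValueError(
            "fit_error_model requires alignments with CIGAR strings (=/X or M ops)"
        )
    # Laplace-smoothed transitions, self-transitions impossible (runs maximal)
    trans = trans_counts + laplace
    np.fill_diagonal(trans, 0.0)
    trans = trans / trans.sum(axis=1, keepdims=True)
    run_lengths = {}
    for st in STATES:
        obs = np.asarray(run_obs[st], dtype=int)
        if obs.size == 0:
            run_lengths[st] = (np.array([1]), np.array([1.0]))
        else:
            vals, counts = np.unique(obs, return_counts=True)
            run_lengths[st] = (vals, counts / counts.sum())
    comp = base_counts / base_counts.sum() if base_counts.sum() > 0 else np.full(4, 0.25)
    quality_hists = None
    if any(qual_obs[st] for st in STATES):
        quality_hists = {}
        for st in ("match", "mismatch", "insertion"):
            obs = np.asarray(qual_obs[st], dtype=int)
            if obs.size == 0:
                obs = np.array([12])  # uninformative default
            vals, counts = np.unique(obs, return_counts=True)
            quality_hists[st] = (vals, counts / counts.sum())
    return ErrorModel(
        transitions=trans,
        run_lengths=run_lengths,
        base_composition=comp,
        quality_hists=quality_hists,
    )


class _Pool:
    """Chunked presampling so per-event draws stay cheap in the hot loop.

    Starts small and doubles on refill, so short templates do not pay for a
    large up-front draw.
    """

    def __init__(self, sampler, size=64):
        self._sampler = sampler
        self._size = size
        self._buf = sampler(size)
        self._i = 0

    def next(self):
        if self._i >= len(self._buf):
            self._size = min(self._size * 2, _POOL)
            self._buf = self._sampler(self._size)
            self._i = 0
        v = self._buf[self._i]
        self._i += 1
        return v


def introduce_errors(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[tuple]]:
    """Mutate a template per the event chain; returns (read, event log).

    The log holds ``(type, template_pos, length, emitted)`` tuples where
    *emitted* carries the substituted/inserted bases (None for match and
    deletion); replaying the log against the template reproduces the read
    exactly.
    """
    if not seq:
        raise ValueError("empty template sequence")
    run_pools = {
        st: _Pool(lambda n, v=vals, p=probs: rng.choice(v, size=n, p=p))
        for st, (vals, probs) in model.run_lengths.items()
    }
    trans_pools = {
        st: _Pool(lambda n, row=model.transitions[_SIDX[st]]: rng.choice(4, size=n, p=row))
        for st in STATES
    }
    sub_pool = _Pool(lambda n: rng.integers(1, 4, size=n))  # offset to a different base
    comp = model.base_composition
    ins_pool = _Pool(lambda n: rng.choice(4, size=n, p=comp))
    base_idx = {b: i for i, b in enumerate("ACGT")}

    out: list[str] = []
    log: list[tuple] = []
    pos, n = 0, len(seq)
    state = "match"
    while pos < n:
        ln = int(run_pools[state].next())
        if state == "match":
            ln = min(ln, n - pos)
            out.append(seq[pos : pos + ln])
            log.append(("match", pos, ln, None))
            pos += ln
        elif state == "mismatch":
            ln = min(ln, n - pos)
            emitted = "".join(
                _BASES[(base_idx.get(seq[pos + i], 0) + int(sub_pool.next())) % 4]
                for i in range(ln)
            )
            out.append(emitted)
            log.append(("mismatch", pos, ln, emitted))
            pos += ln
        elif state == "insertion":
            emitted = "".join(_BASES[int(ins_pool.next())] for _ in range(ln))
            out.append(emitted)
            log.append(("insertion", pos, ln, emitted))
        else:  # deletion
            ln = min(ln, n - pos)
            log.append(("deletion", pos, ln, None))
            pos += ln
        state = STATES[int(trans_pools[state].next())]
    return "".join(out), log


_STATE_OP = {"match": "=", "mismatch": "X", "insertion": "I", "deletion": "D"}


def log_to_cigar(log: Sequence[tuple]) -> str:
    """Render an event log as a CIGAR string with =/X ops."""
    return "".join(f"{ln}{_STATE_OP[op]}" for op, _pos, ln, _em in log)


def replay_log(template: str, log: Sequence[tuple]) -> str:
    """Reapply an event log to its template, reproducing the mutated read."""
    out = []
    for op, pos, ln, emitted in log:
        if op == "match":
            out.append(template[pos : pos + ln])
        elif op in ("mismatch", "insertion"):
            out.append(emitted)
        elif op == "deletion":
            pass
        else:
            raise ValueError(f"unknown event type {op!r}")
    return "".join(out)


def assign_qualities(
    log: Sequence[tuple], model: ErrorModel, rng: np.random.Generator
) -> list[int]:
    """Per-base Phred qualities drawn from event-type-conditional histograms."""
    if model.quality_hists is None:
        raise ValueError(
            "model has no quality histograms (trained without FASTQ); write FASTA instead"
        )
    quals: list[int] = []
    for op, _pos, ln, _em in log:
        if op == "deletion":
            continue
        vals, probs = model.quality_hists[op]
        quals.extend(int(q) for q in rng.choice(vals, size=ln, p=probs))
    return quals
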