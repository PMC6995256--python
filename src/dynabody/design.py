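"""Pseudo-randomized block schedule for the dynamic body localizer.

One run is 48 blocks of 10 s: 18 body blocks (emotional whole-body movement,
balanced across three emotions), 18 moving-object blocks and 12 blank
baseline blocks.  The ordering derives from a maximal-length shift-register
sequence (m-sequence) over GF(3), whose flat autocorrelation decorrelates
condition history; because one period of a ternary m-sequence never matches
the 18/18/12 composition exactly, the cyclic sequence is tiled to 48 blocks
and repaired with a minimal number of edits chosen to keep neighbouring
blocks decorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BODY_CONDITIONS = ("body_angry", "body_happy", "body_neutral")
DEFAULT_COUNTS = {"body": 18, "object": 18, "baseline": 12}
DEFAULT_EMOTIONS = ("angry", "happy", "neutral")
BLOCK_DURATION_S = 10.0
N_BLOCKS = 48
MAX_RUN = 3  # hard cap on consecutive same-condition blocks

#: Primitive feedback taps (c1..ck) for s_n = sum_i c_i * s_{n-i} mod base,
#: verified exhaustively (full period from every nonzero state).
DEFAULT_TAPS = {
    (2, 2): (1, 1),
    (2, 3): (0, 1, 1),
    (2, 4): (0, 0, 1, 1),
    (3, 2): (1, 1),
    (3, 3): (0, 1, 2),
    (3, 4): (0, 0, 1, 1),
}


@dataclass
class MSequence:
    base: int
    order: int
    taps: tuple
    symbols: np.ndarray

    @property
    def period(self) -> int:
        return self.base**self.order - 1


@dataclass
class Block:
    condition: str
    onset_s: float
    duration_s: float = BLOCK_DURATION_S
    clip_ids: tuple | None = None


@dataclass
class BlockSchedule:
    blocks: list
    tr_s: float = 2.6

    def __post_init__(self) -> None:
        onsets = [b.onset_s for b in self.blocks]
        if any(b2 <= b1 for b1, b2 in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        for b in self.blocks:
            if b.condition == "baseline" and b.clip_ids is not None:
                raise ValueError("baseline blocks carry no clips")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def total_duration_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    @property
    def conditions(self) -> list:
        return [b.condition for b in self.blocks]

    def condition_blocks(self, group: str) -> list:
        """Blocks in a condition group: 'body', 'object' or 'baseline'."""
        if group == "body":
            return [b for b in self.blocks if b.condition.startswith("body")]
        return [b for b in self.blocks if b.condition == group]

    def stimulus_blocks(self) -> list:
        return [b for b in self.blocks if b.condition != "baseline"]


def generate_msequence(
    base: int = 3,
    order: int = 3,
    taps: tuple | None = None,
    seed_state: tuple | None = None,
) -> MSequence:
    """Run a linear feedback shift register over GF(base) for one full period.

    ``taps`` are the feedback coefficients ``(c1..ck)`` of the recurrence
    ``s_n = (c1 s_{n-1} + ... + ck s_{n-k}) mod base``; they must come from a
    primitive polynomial so every nonzero k-tuple of states occurs exactly
    once per period ``base**order - 1``.  Non-primitive taps are detected by
    the realized period and rejected.
    """
    if taps is None:
        try:
            taps = DEFAULT_TAPS[(base, order)]
        except KeyError:
            raise ValueError(f"no default taps for base={base}, order={order}")
    taps = tuple(int(t) % base for t in taps)
    if len(taps) != order:
        raise ValueError("taps length must equal order")
    if seed_state is None:
        seed_state = (0,) * (order - 1) + (1,)
    seed_state = tuple(int(s) % base for s in seed_state)
    if not any(seed_state):
        raise ValueError("seed state must be nonzero")

    period = base**order - 1
    rev_taps = taps[::-1]  # align with state stored oldest..newest
    state = seed_state
    out = list(state)
    for _ in range(period - order):
        nxt = sum(c * s for c, s in zip(rev_taps, state)) % base
        out.append(nxt)
        state = state[1:] + (nxt,)
    realized = _state_period(base, rev_taps, seed_state)
    if realized != period:
        raise ValueError(
            f"taps {taps} are not primitive over GF({base}): "
            f"realized period {realized} != {period}"
        )
    return MSequence(base=base, order=order, taps=taps, symbols=np.array(out))


def _state_period(base: int, rev_taps: tuple, seed_state: tuple) -> int:
    state = seed_state
    for n in range(1, base ** len(rev_taps) + 1):
        nxt = sum(c * s for c, s in zip(rev_taps, state)) % base
        state = state[1:] + (nxt,)
        if state == seed_state:
            return n
    return -1


def _adjacent_same(seq) -> int:
    return sum(a == b for a, b in zip(seq, seq[1:]))


def _max_run(seq) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _run_penalty(seq, cap: int = MAX_RUN) -> int:
    pen = run = 0
    prev = None
    for c in seq:
        run = run + 1 if c == prev else 1
        if run > cap:
            pen += 1
        prev = c
    return pen


def _repair_counts(seq: list, target: dict) -> list:
    """Edit symbols until counts match ``target``, one minimal edit at a time.

    Each edit converts one surplus-condition block into a deficit condition,
    choosing the position that minimizes lag-1 condition repeats with a hard
    penalty on runs longer than MAX_RUN; ties resolve to the earliest index.
    """
    seq = list(seq)
    while True:
        counts = {c: seq.count(c) for c in target}
        surplus = [c for c in target if counts[c] > target[c]]
        deficit = [c for c in target if counts[c] < target[c]]
        if not surplus:
            break
        best = None
        for i, c in enumerate(seq):
            if c not in surplus:
                continue
            for d in deficit:
                trial = seq[:i] + [d] + seq[i + 1 :]
                key = (_adjacent_same(trial) + 1000 * _run_penalty(trial), i, d)
                if best is None or key < best:
                    best = key
        seq[best[1]] = best[2]
    return seq


def _enforce_run_cap(seq: list) -> list:
    """Swap blocks between positions until no run exceeds MAX_RUN."""
    seq = list(seq)
    for _ in range(100):
        if _run_penalty(seq) == 0:
            return seq
        # locate the first over-long run and swap its interior element
        run_start, run_len = 0, 1
        pos = None
        for i in range(1, len(seq)):
            if seq[i] == seq[i - 1]:
                run_len += 1
                if run_len > MAX_RUN:
                    pos = i
                    break
            else:
                run_len = 1
        best = None
        for j, c in enumerate(seq):
            if c == seq[pos]:
                continue
            trial = list(seq)
            trial[pos], trial[j] = trial[j], trial[pos]
            score = (_run_penalty(trial), _adjacent_same(trial), j)
            if best is None or score < best[:3]:
                best = score + (trial,)
        seq = best[3]
    raise RuntimeError("could not satisfy the run-length cap")


def build_schedule(
    mseq: MSequence | None = None,
    counts: dict | None = None,
    emotions: tuple = DEFAULT_EMOTIONS,
    emotion_counts: dict | None = None,
    seed: int = 0,
    block_duration_s: float = BLOCK_DURATION_S,
    tr_s: float = 2.6,
    clip_pool: dict | None = None,
) -> BlockSchedule:
    """Build the 48-block schedule from a tiled, repaired m-sequence.

    Symbol 0 (the under-represented symbol of a ternary m-sequence) maps to
    baseline; the two nonzero symbols map to body and object (assignment,
    sequence rotation and clip dealing are drawn from ``seed``).  Emotions
    rotate over the body blocks in balanced counts.  ``clip_pool`` optionally
    maps ``"body"``/``"object"`` to clip-id lists dealt 5 per block.
    """
    counts = dict(counts or DEFAULT_COUNTS)
    if sum(counts.values()) != N_BLOCKS:
        raise ValueError(f"condition counts must sum to {N_BLOCKS}")
    emotion_counts = dict(
        emotion_counts or {e: counts["body"] // len(emotions) for e in emotions}
    )
    if sum(emotion_counts.values()) != counts["body"]:
        raise ValueError("emotion counts must sum to the body-block count")

    rng = np.random.default_rng(seed)
    if mseq is None:
        mseq = generate_msequence(base=3, order=3)
    symbols = np.roll(mseq.symbols, int(rng.integers(mseq.symbols.size)))
    tiled = np.resize(symbols, N_BLOCKS)
    body_sym, obj_sym = (1, 2) if rng.integers(2) == 0 else (2, 1)
    mapping = {0: "baseline", body_sym: "body", obj_sym: "object"}
    seq = [mapping[int(s)] for s in tiled]
    seq = _repair_counts(seq, counts)
    seq = _enforce_run_cap(seq)

    remaining = dict(emotion_counts)
    emotion_cycle = []
    while any(remaining.values()):
        for e in emotions:
            if remaining[e] > 0:
                emotion_cycle.append(e)
                remaining[e] -= 1
    pools = {}
    if clip_pool:
        for cond, ids in clip_pool.items():
            ids = list(ids)
            rng.shuffle(ids)
            pools[cond] = ids

    blocks = []
    e_idx = 0
    deal = {"body": 0, "object": 0}
    for i, cond in enumerate(seq):
        onset = i * block_duration_s
        if cond == "baseline":
            blocks.append(Block("baseline", onset, block_duration_s, None))
            continue
        if cond == "body":
            label = f"body_{emotion_cycle[e_idx]}"
            e_idx += 1
        else:
            label = "object"
        if cond in pools:
            pool = pools[cond]
            ids = tuple(pool[(deal[cond] + j) % len(pool)] for j in range(5))
        else:
            ids = tuple(f"{cond}_clip{deal[cond] + j:03d}" for j in range(5))
        deal[cond] += 5
        blocks.append(Block(label, onset, block_duration_s, ids))

    sched = BlockSchedule(blocks=blocks, tr_s=tr_s)
    _validate_schedule(sched, counts, emotion_counts)
    return sched


def _validate_schedule(s: BlockSchedule, counts: dict, emotion_counts: dict) -> None:
    assert s.n_blocks == N_BLOCKS
    assert len(s.condition_blocks("body")) == counts["body"]
    assert len(s.condition_blocks("object")) == counts["object"]
    assert len(s.condition_blocks("baseline")) == counts["baseline"]
    groups = ["body" if c.startswith("body") else c for c in s.conditions]
    assert _max_run(groups) <= MAX_RUN
    for emo, k in emotion_counts.items():
        assert sum(1 for b in s.blocks if b.condition == f"body_{emo}") == k


def design_efficiency(
    schedule: BlockSchedule, n_volumes: int = 246, tr_s: float | None = None
) -> dict:
    """Regressor correlations and contrast efficiency of a schedule.

    Convolves body and object boxcars with the canonical HRF, reports the
    pairwise regressor correlations and the efficiency
    ``1 / (c' (X'X)^-1 c)`` of the body-object contrast.
    """
    from . import glm  # local import avoids a module cycle

    tr_s = tr_s or schedule.tr_s
    body = glm.condition_regressor(schedule, "body", n_volumes, tr_s)
    obj = glm.condition_regressor(schedule, "object", n_volumes, tr_s)
    X = np.column_stack([body, obj, np.ones(n_volumes)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (degenerate schedule)")
    corr = float(np.corrcoef(body, obj)[0, 1])
    c = np.array([1.0, -1.0, 0.0])
    eff = float(1.0 / (c @ np.linalg.inv(X.T @ X) @ c))
    return {"corr_body_object": corr, "efficiency": eff}


def write_events(schedule: BlockSchedule, path) -> pd.DataFrame:
    """Write a BIDS-style events table (onset, duration, trial_type, clip_ids)."""
    rows = []
    for b in schedule.blocks:
        rows.append(
            {
                "onset": b.onset_s,
                "duration": b.duration_s,
                "trial_type": b.condition,
                "clip_ids": "|".join(b.clip_ids) if b.clip_ids else "n/a",
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_events(path, tr_s: float = 2.6) -> BlockSchedule:
    """Read an events table written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    blocks = []
    for _, row in df.iterrows():
        ids = None if row["clip_ids"] == "n/a" else tuple(str(row["clip_ids"]).split("|"))
        blocks.append(Block(row["trial_type"], float(row["onset"]), float(row["duration"]), ids))
    return BlockSchedule(blocks=blocks, tr_s=tr_s)
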