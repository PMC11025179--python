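"""Benchmark simulation with known ground truth.

The generator emulates PCR duplication with ambiguous base calls: draw a set
of distinct random parental sequences, sample reads from them uniformly with
replacement (reads sharing a parent are PCR duplicates), then mask a fixed
number of positions per read to 'N', standing in for low-quality base calls.
Because each read remembers its parent, the true deduplicated-set size — the
number of distinct parents actually sampled — is known exactly, which is
what lets accuracy be scored at all.

When ``n_reads == n_parents == n``, the expected fraction of parents sampled
at least once is 1 - (1 - 1/n)^n → 1 - 1/e ≈ 63.2% for large n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import DNA, Alphabet, SeqRecord
from .dedup import Method, dedup
from .errors import InfeasibleConfigError


@dataclass(frozen=True)
class SimConfig:
    """One simulation condition.

    ``n_mask`` is the exact number of positions masked per read; pass
    ``mask_fraction`` instead to derive it from the read length (rounded to
    the nearest integer).  Defaults mirror a typical benchmark condition:
    200-bp reads, as many parents as reads, 5% of bases masked.
    """

    n_parents: int = 10_000
    n_reads: int = 10_000
    read_length: int = 200
    n_mask: Optional[int] = None
    mask_fraction: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 1 or self.n_reads < 1 or self.read_length < 1:
            raise InfeasibleConfigError("n_parents, n_reads, read_length must be >= 1")
        if self.n_mask is not None and self.mask_fraction is not None:
            raise InfeasibleConfigError("give n_mask or mask_fraction, not both")
        if self.n_mask is None:
            frac = 0.05 if self.mask_fraction is None else self.mask_fraction
            if not 0 <= frac <= 1:
                raise InfeasibleConfigError("mask_fraction must be in [0, 1]")
            object.__setattr__(self, "n_mask", int(round(frac * self.read_length)))
        if not 0 <= self.n_mask <= self.read_length:
            raise InfeasibleConfigError(
                f"n_mask={self.n_mask} outside [0, read_length={self.read_length}]"
            )
        # 4^length distinct parents is the hard ceiling for uniqueness
        if self.read_length < 64 and self.n_parents > 4**self.read_length:
            raise InfeasibleConfigError(
                f"cannot draw {self.n_parents} distinct parents of length "
                f"{self.read_length} (only {4**self.read_length} exist)"
            )


@dataclass
class SimTruth:
    """Ground truth for one simulated read set."""

    parents: list[str]
    parent_of: np.ndarray  # per-read parent index
    masked_positions: list[tuple[int, ...]]

    def to_frame(self) -> pd.DataFrame:
        """Truth table: read_id, parent_id, comma-joined masked positions."""
        return pd.DataFrame(
            {
                "read_id": [f"read{i}" for i in range(len(self.parent_of))],
                "parent_id": [f"parent{j}" for j in self.parent_of],
                "masked_positions": [
                    ",".join(map(str, pos)) for pos in self.masked_positions
                ],
            }
        )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _draw_parents(rng: np.random.Generator, n: int, length: int) -> list[str]:
    # Rejection sampling keeps the parent set distinct; collisions are
    # essentially impossible for length >= 30 but short toy lengths need it.
    seen: set[bytes] = set()
    parents: list[str] = []
    while len(parents) < n:
        batch = _BASES[rng.integers(0, 4, size=(n - len(parents), length))]
        for row in batch.view(f"S{length}").ravel():
            if row not in seen:
                seen.add(row)
                parents.append(row.decode())
                if len(parents) == n:
                    break
    return parents


def simulate_reads(config: SimConfig) -> tuple[list[SeqRecord], SimTruth]:
    """Generate reads plus ground truth, fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    parents = _draw_parents(rng, config.n_parents, L)
    parent_of = rng.integers(0, config.n_parents, size=config.n_reads)

    k = config.n_mask
    records: list[SeqRecord] = []
    masked: list[tuple[int, ...]] = []
    if k > 0:
        # first k ranks of a random permutation per read = k distinct positions
        positions = np.argsort(rng.random((config.n_reads, L)), axis=1)[:, :k]
        positions.sort(axis=1)
    for i, pj in enumerate(parent_of):
        seq = parents[pj]
        if k > 0:
            pos = tuple(int(p) for p in positions[i])
            chars = list(seq)
            for p in pos:
                chars[p] = "N"
            seq = "".join(chars)
        else:
            pos = ()
        masked.append(pos)
        records.append(
            SeqRecord(
                read_id=f"read{i}",
                seq=seq,
                n_ambiguous=k,
                input_rank=i,
            )
        )
    return records, SimTruth(parents=parents, parent_of=parent_of, masked_positions=masked)


def ground_truth_size(truth: SimTruth) -> int:
    """Number of distinct parents actually sampled = true deduplicated-set size."""
    return int(np.unique(truth.parent_of).size)


def run_benchmark(
    configs: Sequence[SimConfig],
    methods: Sequence[Method] = ("trie", "pairwise"),
    replicates: int = 3,
    seed: int = 0,
    alphabet: Alphabet = DNA,
) -> pd.DataFrame:
    """Run each config x method x replicate and tabulate sizes and work counters.

    Replicate seeds are derived deterministically from ``seed`` and the
    config's own seed, so the whole table is a pure function of its inputs.
    Wall-clock and memory are deliberately not measured: the comparison and
    node-visit counters are the hardware-independent cost proxies.
    """
    rows = []
    for ci, config in enumerate(configs):
        for rep in range(replicates):
            child = np.random.SeedSequence([seed, config.seed, ci, rep])
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            cfg = SimConfig(
                n_parents=config.n_parents,
                n_reads=config.n_reads,
                read_length=config.read_length,
                n_mask=config.n_mask,
                seed=rep_seed,
            )
            records, truth = simulate_reads(cfg)
            truth_size = ground_truth_size(truth)
            for method in methods:
                result = dedup(records, method=method, alphabet=alphabet)
                rows.append(
                    {
                        "n": cfg.n_reads,
                        "length": cfg.read_length,
                        "n_mask": cfg.n_mask,
                        "n_pct": 100.0 * cfg.n_mask / cfg.read_length,
                        "method": method,
                        "replicate": rep,
                        "seed": rep_seed,
                        "dedup_size": len(result),
                        "ground_truth": truth_size,
                        "comparisons": result.stats.comparisons,
                        "node_visits": result.stats.node_visits,
                    }
                )
    return pd.DataFrame(rows)


def loglog_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """Least-squares slope of log10(y) on log10(x) — the scaling exponent."""
    lx = np.log10(np.asarray(x, dtype=float))
    ly = np.log10(np.asarray(y, dtype=float))
    return float(np.polyfit(lx, ly, 1)[0])
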