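"""Generation-probability-dependent thymic selection.

Only about a third of productive rearrangements survive thymic selection,
and survival is biased by the generation probability P(sigma).  The model
bins log10 P(sigma) into 100 equal bins on [-50, 0], merges sparse adjacent
bins until every merged bin holds at least 1% of the empirical observations,
and assigns each merged bin the density ratio

    f = (empirical bin fraction) / (pre-selection bin fraction),

so a chain survives with probability p_selected = f * overall_factor
(default overall_factor = 1/3).  Applying the model to the pre-selection
pool then reproduces the empirical P(sigma) density by construction.

Two application modes exist: ``memoized`` (default) stores one Bernoulli
decision per distinct sequence so repeated productions of the same sequence
share a fate; ``per-event`` decides independently for every copy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .vdj import ChainRecord

__all__ = [
    "SelectionModel",
    "train_selection",
    "selection_probability",
    "apply_selection",
    "flat_selection",
    "selection_mask",
]

LOG10_PGEN_RANGE = (-50.0, 0.0)
N_BASE_BINS = 100


@dataclass
class SelectionModel:
    locus: str
    bin_edges: np.ndarray  # merged-bin boundaries over log10 pgen
    factors: np.ndarray  # density ratio f per merged bin
    overall_factor: float = 1.0 / 3.0
    mode: str = "memoized"  # or "per-event"
    _memo: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if len(self.bin_edges) != len(self.factors) + 1:
            raise ValueError("need one more edge than factors")
        if np.any(self.factors < 0):
            raise ValueError("selection factors must be >= 0")
        if not 0 < self.overall_factor <= 1:
            raise ValueError("overall_factor must be in (0, 1]")
        if self.mode not in ("memoized", "per-event"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def factor(self, pgen) -> np.ndarray:
        lp = np.log10(np.asarray(pgen, dtype=float))
        idx = np.clip(
            np.searchsorted(self.bin_edges, lp, side="right") - 1,
            0,
            len(self.factors) - 1,
        )
        return self.factors[idx]

    def reset_memo(self) -> None:
        self._memo.clear()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "locus": self.locus,
                    "bin_edges": self.bin_edges.tolist(),
                    "factors": self.factors.tolist(),
                    "overall_factor": self.overall_factor,
                    "mode": self.mode,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SelectionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            locus=d["locus"],
            bin_edges=np.asarray(d["bin_edges"]),
            factors=np.asarray(d["factors"]),
            overall_factor=d["overall_factor"],
            mode=d["mode"],
        )


def flat_selection(locus: str, overall_factor: float = 1.0 / 3.0) -> SelectionModel:
    """Selection model with f = 1 everywhere (pure overall thinning)."""
    return SelectionModel(
        locus, np.array(LOG10_PGEN_RANGE), np.array([1.0]), overall_factor
    )


def train_selection(
    empirical_pgens,
    pregen_pgens,
    overall_factor: float = 1.0 / 3.0,
    locus: str = "alpha",
    min_occupancy: float = 0.01,
) -> SelectionModel:
    """Fit per-bin selection factors from observed versus pre-selection
    generation probabilities.

    Bins are merged left-to-right (from low log10 pgen, where observations
    are sparse) until each merged bin carries at least ``min_occupancy`` of
    the empirical observations; a trailing underfull bin is folded into its
    predecessor.
    """
    emp = np.log10(np.asarray(empirical_pgens, dtype=float))
    pre = np.log10(np.asarray(pregen_pgens, dtype=float))
    if len(emp) == 0 or len(pre) == 0:
        raise ValueError("both pgen sets must be nonempty")
    base_edges = np.linspace(*LOG10_PGEN_RANGE, N_BASE_BINS + 1)
    emp_hist, _ = np.histogram(emp, bins=base_edges)
    pre_hist, _ = np.histogram(pre, bins=base_edges)
    if emp_hist.sum() == 0 or pre_hist.sum() == 0:
        raise ValueError("pgen values fall outside the binned range")
    need = min_occupancy * emp_hist.sum()

    edges = [base_edges[0]]
    emp_counts, pre_counts = [], []
    acc_e = acc_p = 0
    for b in range(N_BASE_BINS):
        acc_e += emp_hist[b]
        acc_p += pre_hist[b]
        if acc_e >= need:
            edges.append(base_edges[b + 1])
            emp_counts.append(acc_e)
            pre_counts.append(acc_p)
            acc_e = acc_p = 0
    if acc_e > 0 or acc_p > 0 or len(edges) == 1:
        if len(emp_counts) == 0:
            raise ValueError("empirical observations never reach the occupancy rule")
        emp_counts[-1] += acc_e
        pre_counts[-1] += acc_p
        edges[-1] = base_edges[-1]
    edges = np.asarray(edges)
    edges[-1] = base_edges[-1]
    emp_frac = np.asarray(emp_counts, float) / emp_hist.sum()
    pre_frac = np.asarray(pre_counts, float) / pre_hist.sum()
    if np.all(pre_frac == 0):
        raise ValueError("empirical and pre-selection supports do not overlap")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(pre_frac > 0, emp_frac / np.maximum(pre_frac, 1e-300), 0.0)
    return SelectionModel(locus, edges, f, overall_factor)


def selection_probability(model: SelectionModel, pgen) -> np.ndarray:
    """p_selected = f(bin of log10 pgen) * overall_factor, clipped to [0, 1]."""
    pgen_arr = np.asarray(pgen, dtype=float)
    if np.any(pgen_arr <= 0) or np.any(pgen_arr > 1):
        raise ValueError("pgen must lie in (0, 1]")
    return np.minimum(model.factor(pgen_arr) * model.overall_factor, 1.0)


def apply_selection(
    chains: list[ChainRecord], model: SelectionModel, rng: np.random.Generator
) -> list[ChainRecord]:
    """Thin a pre-selection chain list through the selection model.

    ``memoized`` mode draws one decision per distinct (V, J, junction)
    sequence and reuses it for every copy, so repeated productions of the
    same sequence survive or die together; ``per-event`` mode decides
    independently per copy.
    """
    kept = []
    for chain in chains:
        if chain.locus != model.locus:
            raise ValueError("selection model locus does not match the chains")
        p = float(selection_probability(model, chain.pgen))
        if model.mode == "memoized":
            key = (chain.v_call, chain.j_call, chain.junction_nt)
            decision = model._memo.get(key)
            if decision is None:
                decision = bool(rng.random() < p)
                model._memo[key] = decision
        else:
            decision = bool(rng.random() < p)
        if decision:
            kept.append(chain)
    return kept


def selection_mask(
    pgens: np.ndarray,
    seq_ids: np.ndarray,
    model: SelectionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised memoized selection over parallel arrays of pgens and
    distinct-sequence ids: one Bernoulli draw per distinct id."""
    p = selection_probability(model, pgens)
    if model.mode == "per-event":
        return rng.random(len(p)) < p
    uniq, first = np.unique(seq_ids, return_index=True)
    draw = rng.random(len(uniq)) < p[first]
    decision_of = dict(zip(uniq.tolist(), draw.tolist()))
    return np.fromiter((decision_of[s] for s in seq_ids), bool, len(seq_ids))
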