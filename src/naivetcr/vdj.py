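"""Reduced V(D)J-like recombination model with exactly computable generation
probabilities.

A rearranged chain is built as ``V-tail | inserted nucleotides | J-head``,
where a number of bases may first be deleted from the 3' end of the V tail
and the 5' end of the J head.  Because many different (deletion, insertion)
scenarios can produce the same junction sequence, the generation probability
P(sigma) of a sequence sigma = (V, J, junction) is the *sum* of scenario
probabilities over every scenario consistent with the junction.  The model is
deliberately small (no D segment, short junctions) so that this sum can be
evaluated exactly by enumeration, giving every synthetic chain an exact
ground-truth pgen.  The alpha and beta default parameterisations differ in
their insertion-length mass, which puts their pgen spectra several orders of
magnitude apart, mirroring the real alpha/beta asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Segment",
    "SyntheticVDJModel",
    "ChainRecord",
    "pgen",
    "min_insertions",
    "is_productive",
    "generate_rearrangement",
    "generate_batch",
    "default_model",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Segment:
    """A V tail or J head: label, germline nucleotides, usage probability."""

    label: str
    seq: str
    prob: float


@dataclass(frozen=True)
class ChainRecord:
    """One TCR alpha or beta rearrangement with its generative ground truth."""

    locus: str
    v_call: str
    j_call: str
    junction_nt: str
    n_insertions_true: int
    n_insertions_min: int
    pgen: float

    def __post_init__(self) -> None:
        if self.pgen <= 0:
            raise ValueError("pgen must be positive for a generated chain")
        if self.n_insertions_min > self.n_insertions_true:
            raise ValueError("minimal insertions cannot exceed the true count")


class SyntheticVDJModel:
    """Recombination model over small V/J segment sets.

    Parameters
    ----------
    locus:
        ``"alpha"`` or ``"beta"``.
    v_segments, j_segments:
        Segment sets; usage probabilities must each sum to 1.
    deletion_probs:
        ``P(d)`` for ``d = 0..max_deletions`` deleted bases, applied
        independently to the V and J side.
    insertion_probs:
        ``P(L)`` for ``L = 0..L_max`` inserted junction bases.
    base_probs:
        Per-base probabilities (A, C, G, T) of each inserted nucleotide,
        uniform by default.
    """

    def __init__(
        self,
        locus: str,
        v_segments: Sequence[Segment],
        j_segments: Sequence[Segment],
        deletion_probs: Sequence[float],
        insertion_probs: Sequence[float],
        base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> None:
        if locus not in ("alpha", "beta"):
            raise ValueError(f"unknown locus {locus!r}")
        self.locus = locus
        self.v_segments = list(v_segments)
        self.j_segments = list(j_segments)
        self.deletion_probs = np.asarray(deletion_probs, dtype=float)
        self.insertion_probs = np.asarray(insertion_probs, dtype=float)
        self.base_probs = np.asarray(base_probs, dtype=float)
        self._v_by_label = {s.label: s for s in self.v_segments}
        self._j_by_label = {s.label: s for s in self.j_segments}
        self._validate()

    def _validate(self) -> None:
        for name, vec in (
            ("V usage", np.array([s.prob for s in self.v_segments])),
            ("J usage", np.array([s.prob for s in self.j_segments])),
            ("deletion", self.deletion_probs),
            ("insertion", self.insertion_probs),
            ("base", self.base_probs),
        ):
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} probabilities must be >= 0 and sum to 1")
        max_del = self.max_deletions
        for seg in (*self.v_segments, *self.j_segments):
            if set(seg.seq) - set(BASES):
                raise ValueError(f"segment {seg.label} has non-ACGT characters")
            if len(seg.seq) <= max_del:
                raise ValueError(
                    f"segment {seg.label} shorter than max deletions + 1"
                )
            for k in range(0, len(seg.seq) - 2, 3):
                if seg.seq[k : k + 3] in STOP_CODONS:
                    raise ValueError(f"segment {seg.label} has an in-frame stop")

    @property
    def max_deletions(self) -> int:
        return len(self.deletion_probs) - 1

    @property
    def max_insertions(self) -> int:
        return len(self.insertion_probs) - 1

    def v(self, label: str) -> Segment:
        return self._v_by_label[label]

    def j(self, label: str) -> Segment:
        return self._j_by_label[label]

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "v_segments": [[s.label, s.seq, float(s.prob)] for s in self.v_segments],
            "j_segments": [[s.label, s.seq, float(s.prob)] for s in self.j_segments],
            "deletion_probs": [float(p) for p in self.deletion_probs],
            "insertion_probs": [float(p) for p in self.insertion_probs],
            "base_probs": [float(p) for p in self.base_probs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticVDJModel":
        return cls(
            locus=d["locus"],
            v_segments=[Segment(*row) for row in d["v_segments"]],
            j_segments=[Segment(*row) for row in d["j_segments"]],
            deletion_probs=d["deletion_probs"],
            insertion_probs=d["insertion_probs"],
            base_probs=d.get("base_probs", (0.25, 0.25, 0.25, 0.25)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticVDJModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_model(locus: str) -> SyntheticVDJModel:
    """Load the packaged default alpha or beta model."""
    fname = {"alpha": "alpha_model.yaml", "beta": "beta_model.yaml"}[locus]
    ref = resources.files("naivetcr.data").joinpath(fname)
    with ref.open() as fh:
        return SyntheticVDJModel.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# exact generation probability

def _scenarios(model: SyntheticVDJModel, v: Segment, j: Segment, junction_nt: str):
    """Yield (n_insertions, scenario probability given V and J) for every
    (V-deletion, J-deletion) scenario consistent with the junction."""
    n = len(junction_nt)
    ins_probs = model.insertion_probs
    base_probs = model.base_probs
    for dv, p_dv in enumerate(model.deletion_probs):
        if p_dv == 0.0:
            continue
        prefix_len = len(v.seq) - dv
        if n < prefix_len or not junction_nt.startswith(v.seq[:prefix_len]):
            continue
        for dj, p_dj in enumerate(model.deletion_probs):
            if p_dj == 0.0:
                continue
            suffix_len = len(j.seq) - dj
            mid_len = n - prefix_len - suffix_len
            if mid_len < 0 or mid_len > model.max_insertions:
                continue
            if not junction_nt.endswith(j.seq[dj:]):
                continue
            p_ins = ins_probs[mid_len]
            if p_ins == 0.0:
                continue
            mid = junction_nt[prefix_len : prefix_len + mid_len]
            for b in mid:
                p_ins *= base_probs[_BASE_INDEX[b]]
            if p_ins > 0.0:
                yield mid_len, p_dv * p_dj * p_ins


def pgen(model: SyntheticVDJModel, v_call: str, j_call: str, junction_nt: str) -> float:
    """Exact generation probability of (v_call, j_call, junction_nt).

    Sums the probabilities of every recombination scenario (V deletion,
    J deletion, insertion string) that reproduces the junction; returns 0.0
    when no scenario is consistent.
    """
    v = model.v(v_call)
    j = model.j(j_call)
    total = 0.0
    for _, p in _scenarios(model, v, j, junction_nt):
        total += p
    return v.prob * j.prob * total


def min_insertions(
    model: SyntheticVDJModel, v_call: str, j_call: str, junction_nt: str
) -> int:
    """Minimal number of inserted (non-templated) bases over all scenarios
    consistent with the junction."""
    v = model.v(v_call)
    j = model.j(j_call)
    best = None
    for n_ins, _ in _scenarios(model, v, j, junction_nt):
        if best is None or n_ins < best:
            best = n_ins
    if best is None:
        raise ValueError(
            f"no recombination scenario produces {junction_nt!r} from "
            f"{v_call}/{j_call}"
        )
    return best


def _annotate(
    model: SyntheticVDJModel, v_call: str, j_call: str, junction_nt: str
) -> tuple[float, int]:
    """(pgen, min_insertions) in a single scenario scan."""
    v = model.v(v_call)
    j = model.j(j_call)
    total = 0.0
    best = -1
    for n_ins, p in _scenarios(model, v, j, junction_nt):
        total += p
        if best < 0 or n_ins < best:
            best = n_ins
    if best < 0:
        raise ValueError(
            f"no recombination scenario produces {junction_nt!r} from "
            f"{v_call}/{j_call}"
        )
    return v.prob * j.prob * total, best


def is_productive(junction_nt: str) -> bool:
    """True iff the junction is in frame (length divisible by 3) and free of
    in-frame stop codons (frame 0)."""
    if not junction_nt:
        raise ValueError("empty junction")
    if set(junction_nt) - set(BASES):
        raise ValueError(f"invalid characters in junction {junction_nt!r}")
    if len(junction_nt) % 3 != 0:
        return False
    for k in range(0, len(junction_nt), 3):
        if junction_nt[k : k + 3] in STOP_CODONS:
            return False
    return True


# ---------------------------------------------------------------------------
# sampling

def generate_rearrangement(
    model: SyntheticVDJModel, rng: np.random.Generator
) -> ChainRecord:
    """Sample one rearrangement (V, J, deletions, insertion) and annotate it
    with its exact pgen and minimal-insertion count."""
    v = model.v_segments[
        rng.choice(len(model.v_segments), p=[s.prob for s in model.v_segments])
    ]
    j = model.j_segments[
        rng.choice(len(model.j_segments), p=[s.prob for s in model.j_segments])
    ]
    dv = int(rng.choice(len(model.deletion_probs), p=model.deletion_probs))
    dj = int(rng.choice(len(model.deletion_probs), p=model.deletion_probs))
    L = int(rng.choice(len(model.insertion_probs), p=model.insertion_probs))
    mid = "".join(BASES[k] for k in rng.choice(4, size=L, p=model.base_probs))
    junction = v.seq[: len(v.seq) - dv] + mid + j.seq[dj:]
    return ChainRecord(
        locus=model.locus,
        v_call=v.label,
        j_call=j.label,
        junction_nt=junction,
        n_insertions_true=L,
        n_insertions_min=min_insertions(model, v.label, j.label, junction),
        pgen=pgen(model, v.label, j.label, junction),
    )


def generate_batch(
    model: SyntheticVDJModel,
    n: int,
    rng: np.random.Generator,
    productive_only: bool = False,
    annotate: bool = True,
):
    """Vectorised batch generation.

    Returns a pandas DataFrame with columns ``v_call, j_call, junction_nt,
    n_insertions_true`` plus, when ``annotate`` is set, ``pgen`` and
    ``n_insertions_min`` (computed once per distinct sequence).  With
    ``productive_only`` the non-productive rearrangements are dropped, so the
    returned frame may hold fewer than ``n`` rows.
    """
    import pandas as pd

    v_probs = np.array([s.prob for s in model.v_segments])
    j_probs = np.array([s.prob for s in model.j_segments])
    vi = rng.choice(len(v_probs), size=n, p=v_probs)
    ji = rng.choice(len(j_probs), size=n, p=j_probs)
    dv = rng.choice(len(model.deletion_probs), size=n, p=model.deletion_probs)
    dj = rng.choice(len(model.deletion_probs), size=n, p=model.deletion_probs)
    L = rng.choice(len(model.insertion_probs), size=n, p=model.insertion_probs)
    total_ins = int(L.sum())
    ins_pool = rng.choice(4, size=total_ins, p=model.base_probs)
    offsets = np.concatenate(([0], np.cumsum(L)))

    v_tails = [s.seq for s in model.v_segments]
    j_heads = [s.seq for s in model.j_segments]
    v_labels = [s.label for s in model.v_segments]
    j_labels = [s.label for s in model.j_segments]

    junctions = []
    for k in range(n):
        vt = v_tails[vi[k]]
        jh = j_heads[ji[k]]
        mid = "".join(BASES[b] for b in ins_pool[offsets[k] : offsets[k + 1]])
        junctions.append(vt[: len(vt) - dv[k]] + mid + jh[dj[k] :])

    df = pd.DataFrame(
        {
            "v_call": [v_labels[i] for i in vi],
            "j_call": [j_labels[i] for i in ji],
            "junction_nt": junctions,
            "n_insertions_true": L.astype(int),
        }
    )
    if productive_only:
        keep = np.fromiter(
            (is_productive(s) for s in df["junction_nt"]), bool, len(df)
        )
        df = df[keep].reset_index(drop=True)
    if annotate:
        keys = df["v_call"] + "|" + df["j_call"] + "|" + df["junction_nt"]
        cache: dict[str, tuple[float, int]] = {}
        pg = np.empty(len(df))
        mi = np.empty(len(df), dtype=int)
        for k, key in enumerate(keys):
            hit = cache.get(key)
            if hit is None:
                v_call, j_call, junc = key.split("|")
                hit = _annotate(model, v_call, j_call, junc)
                cache[key] = hit
            pg[k], mi[k] = hit
        df["pgen"] = pg
        df["n_insertions_min"] = mi
    df.attrs["locus"] = model.locus
    return df


def productive_fraction(
    models: Sequence[SyntheticVDJModel], n: int, rng: np.random.Generator
) -> float:
    """Fraction of raw rearrangements (pooled equally over ``models``) whose
    junction passes the in-frame / stop-free productivity filter."""
    n_pass = 0
    n_tot = 0
    for model in models:
        df = generate_batch(model, n // len(models), rng, annotate=False)
        n_tot += len(df)
        n_pass += sum(is_productive(s) for s in df["junction_nt"])
    return n_pass / n_tot
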