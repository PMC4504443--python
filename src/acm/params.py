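"""Model parameters: transition, insertion-slot and emission probabilities.

Emission probabilities are contrasted with a flat background (``bg0``):
unpaired residues uniform over the 4 nucleotides, pairs uniform over the 16
dinucleotides, giving log-odds *bit* scores ``log2(p / bg)``.  Transitions
carry no background model; their contribution to a bit score is the raw
``log2`` probability.  Insertion-region slots are scored by a Bernoulli
open/closed probability per slot; inserted residues themselves are emitted
at background (0 bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelParams", "Priors", "ALPHABET", "BG_UNPAIRED", "BG_PAIR"]

ALPHABET = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
BG_UNPAIRED = 0.25
BG_PAIR = 1.0 / 16.0

NEG_INF = float("-inf")


def pair_cell(x: str, y: str) -> int:
    """Row-major index of dinucleotide (x, y) in a 16-vector."""
    return 4 * BASE_INDEX[x] + BASE_INDEX[y]


@dataclass(frozen=True)
class Priors:
    """Single-pseudocount prior tables added to weighted counts."""

    emission: float = 1.0
    transition: float = 1.0
    slot: float = 1.0


@dataclass
class ModelParams:
    """Trained probabilities of one family model.

    transition
        ``(grammar_index, role) -> probability``; per grammar index the role
        probabilities sum to 1 (fork branches too, unless ``free_forks``).
    slot_open
        ``slot_key -> probability`` that the insertion region is non-empty.
    emission
        ``emission_key -> distribution`` (4-vector for ``un:<col>`` keys,
        16-vector row-major for ``pair:<a>:<b>`` keys), each summing to 1.
    free_forks
        When set, fork-branch choices cost 0 bits (probability treated as 1)
        regardless of the trained branch probabilities.
    """

    transition: dict[tuple[int, str], float]
    slot_open: dict[str, float]
    emission: dict[str, np.ndarray]
    priors: Priors = field(default_factory=Priors)
    free_forks: bool = False
    ins_extend: float = 0.5  # geometric extension probability, model-wide

    # --- log-space accessors (bits) ------------------------------------

    def trans_bits(self, idx: int, role: str) -> float:
        if self.free_forks and role.startswith("branch_"):
            return 0.0
        p = self.transition[(idx, role)]
        return math.log2(p) if p > 0 else NEG_INF

    def region_bits(self, slot: str, length: int) -> float:
        """Bits for an insertion region of ``length`` residues.

        Empty: log2(1 - p_open); otherwise opening plus a geometric length
        term: log2(p_open) + (k-1) log2(q) + log2(1-q).  Residues themselves
        are emitted at background (0 bits).
        """
        p = self.slot_open[slot]
        if length == 0:
            return math.log2(1.0 - p) if p < 1.0 else NEG_INF
        if p <= 0.0:
            return NEG_INF
        q = min(max(self.ins_extend, 1e-12), 1.0 - 1e-12)
        return math.log2(p) + (length - 1) * math.log2(q) + math.log2(1.0 - q)

    def region_coefficients(self, slot: str) -> tuple[float, float, float]:
        """(empty cost, affine offset, per-residue cost): for k >= 1 the
        region costs ``offset + k * per_residue`` bits."""
        q = min(max(self.ins_extend, 1e-12), 1.0 - 1e-12)
        ce = math.log2(q)
        c0 = self.region_bits(slot, 0)
        c1 = self.region_bits(slot, 1) - ce
        return c0, c1, ce

    def emission_bits(self, key: str) -> np.ndarray:
        """Log-odds vector against the flat background."""
        dist = self.emission[key]
        bg = BG_PAIR if dist.size == 16 else BG_UNPAIRED
        with np.errstate(divide="ignore"):
            return np.log2(dist / bg)

    def transition_prob(self, idx: int, role: str) -> float:
        if self.free_forks and role.startswith("branch_"):
            return 1.0
        return self.transition[(idx, role)]

    # --- validation and serialization -----------------------------------

    def validate(self, lhs_roles: dict[int, tuple[str, ...]]) -> None:
        for idx, roles in lhs_roles.items():
            total = sum(self.transition[(idx, r)] for r in roles)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"transition probabilities at index {idx} sum to {total!r}"
                )
        for key, dist in self.emission.items():
            if abs(float(dist.sum()) - 1.0) > 1e-12:
                raise ValueError(f"emission distribution {key} does not sum to 1")
            if (dist < 0).any() or (dist > 1).any():
                raise ValueError(f"emission distribution {key} outside [0, 1]")
        for key, p in self.slot_open.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"slot probability {key} = {p!r} outside [0, 1]")
        if not 0.0 <= self.ins_extend <= 1.0:
            raise ValueError(f"insertion extension probability {self.ins_extend!r}")

    def to_jsonable(self) -> dict:
        return {
            "transition": {f"{i}|{r}": p for (i, r), p in sorted(self.transition.items())},
            "slot_open": dict(sorted(self.slot_open.items())),
            "emission": {k: list(map(float, v)) for k, v in sorted(self.emission.items())},
            "priors": {
                "emission": self.priors.emission,
                "transition": self.priors.transition,
                "slot": self.priors.slot,
            },
            "free_forks": self.free_forks,
            "ins_extend": self.ins_extend,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "ModelParams":
        transition = {}
        for key, p in d["transition"].items():
            idx, role = key.split("|")
            transition[(int(idx), role)] = float(p)
        emission = {k: np.asarray(v, dtype=float) for k, v in d["emission"].items()}
        pr = d.get("priors", {})
        return cls(
            transition=transition,
            slot_open={k: float(v) for k, v in d["slot_open"].items()},
            emission=emission,
            priors=Priors(
                pr.get("emission", 1.0), pr.get("transition", 1.0), pr.get("slot", 1.0)
            ),
            free_forks=bool(d.get("free_forks", False)),
            ins_extend=float(d.get("ins_extend", 0.5)),
        )
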