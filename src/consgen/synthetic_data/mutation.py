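"""Microsatellite mutation models (SMM, IAM, TPM and an SMM/IAM mix).

States are integer repeat counts. IAM-style events create a brand-new
state drawn from a private counter far above the stepwise range so it
can never collide with stepwise states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# New-state counter starts above the stepwise range but low enough that
# repeat counts still convert to Genepop-encodable bp sizes at desk scale.
_IAM_BASE = 300


@dataclass
class MutationModel:
    """Base: strict stepwise mutation (one repeat up or down)."""

    name: str = "SMM"
    _iam_counter: int = field(default=_IAM_BASE, repr=False)

    def _new_state(self) -> int:
        self._iam_counter += 1
        return self._iam_counter

    def mutate(self, state: int, rng: np.random.Generator) -> int:
        step = 1 if rng.random() < 0.5 else -1
        return max(state + step, 2)


@dataclass
class SMM(MutationModel):
    name: str = "SMM"


@dataclass
class IAM(MutationModel):
    """Infinite-alleles: every mutation creates a never-seen state."""

    name: str = "IAM"

    def mutate(self, state: int, rng: np.random.Generator) -> int:
        return self._new_state()


@dataclass
class TPM(MutationModel):
    """Two-phase: single steps, plus geometric multi-step jumps.

    With probability ``1 - p_multi`` a single +/-1 step; otherwise a
    jump of geometric(``geom_p``) repeat units, sign equiprobable.
    """

    p_multi: float = 0.1
    geom_p: float = 0.5
    name: str = "TPM"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_multi <= 1.0):
            raise ValueError("p_multi must lie in [0, 1]")
        if not (0.0 < self.geom_p <= 1.0):
            raise ValueError("geom_p must lie in (0, 1]")

    def mutate(self, state: int, rng: np.random.Generator) -> int:
        if rng.random() < self.p_multi:
            size = int(rng.geometric(self.geom_p))
        else:
            size = 1
        step = size if rng.random() < 0.5 else -size
        return max(state + step, 2)


@dataclass
class SmmIamMix(MutationModel):
    """Mixture: stepwise with probability ``p_smm``, else infinite-alleles.

    This is the generalized-stepwise setting used for bottleneck
    heterozygosity-excess testing with 90% SMM / 10% IAM.
    """

    p_smm: float = 0.9
    name: str = "SMM/IAM mix"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_smm <= 1.0):
            raise ValueError("p_smm must lie in [0, 1]")

    def mutate(self, state: int, rng: np.random.Generator) -> int:
        if rng.random() < self.p_smm:
            step = 1 if rng.random() < 0.5 else -1
            return max(state + step, 2)
        return self._new_state()


def make_model(spec: str, **kwargs) -> MutationModel:
    """Build a model from a config string: smm | iam | tpm | smm_iam_mix."""
    key = spec.strip().lower()
    if key == "smm":
        return SMM()
    if key == "iam":
        return IAM()
    if key == "tpm":
        return TPM(**kwargs)
    if key in ("smm_iam_mix", "mix"):
        return SmmIamMix(**kwargs)
    raise ValueError(f"unknown mutation model {spec!r}")
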