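"""Enumeration of the audiovisual syllable-identification design.

The behavioural task crosses auditory and visual renderings of the syllables
"ba" and "ga" (written B and G) with three signal-to-noise levels per modality
and, for bimodal stimuli, two stimulus onset asynchronies (synchronous, or a
500 ms audio lead).  Bimodal stimuli degrade at most one modality at a time:
clear audio is paired with clear/mid/noisy video, and clear video with
clear/mid/noisy audio, the clear-clear cell counted once.  Together with the
unimodal cells this yields 42 unique conditions; each is presented 25 times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "NA",
    "MODALITIES",
    "PAIRINGS",
    "SNR_LEVELS",
    "SOAS",
    "AV_SNR_COMBOS",
    "Condition",
    "Design",
    "enumerate_design",
    "total_trials",
]

#: Placeholder for a field that does not apply to a condition.
NA = "n/a"

MODALITIES = ("auditory_only", "visual_only", "audiovisual")
#: Stimulus identity: congruent_B = auditory B + visual B, congruent_G
#: likewise, mcgurk = auditory B dubbed onto visual G.  For unimodal
#: conditions the label names the consonant of the modality that is present.
PAIRINGS = ("congruent_B", "congruent_G", "mcgurk")
SNR_LEVELS = ("high", "mid", "low")
SOAS = ("sync", "async")

#: (auditory_snr, visual_snr) cells of the bimodal sub-design: clear audio
#: with progressively noisier video, then clear video with noisier audio.
AV_SNR_COMBOS = (
    ("high", "high"),
    ("high", "mid"),
    ("high", "low"),
    ("mid", "high"),
    ("low", "high"),
)

_CONDITION_COLUMNS = ("modality", "pairing", "auditory_snr", "visual_snr", "soa")


@dataclass(frozen=True)
class Condition:
    """One experimental cell.

    Unimodal cells carry :data:`NA` for the absent modality's SNR and for the
    onset asynchrony.  Bimodal cells always have both SNRs and an SOA, and at
    most one modality degraded below ``high``.
    """

    modality: str
    pairing: str
    auditory_snr: str = NA
    visual_snr: str = NA
    soa: str = NA

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.pairing not in PAIRINGS:
            raise ValueError(f"unknown pairing {self.pairing!r}")
        if self.modality == "auditory_only":
            if self.auditory_snr not in SNR_LEVELS:
                raise ValueError(f"auditory_only requires an auditory SNR, got {self.auditory_snr!r}")
            if self.visual_snr != NA or self.soa != NA:
                raise ValueError("auditory_only conditions must have n/a visual SNR and SOA")
            if self.pairing == "mcgurk":
                raise ValueError("mcgurk pairing requires both modalities")
        elif self.modality == "visual_only":
            if self.visual_snr not in SNR_LEVELS:
                raise ValueError(f"visual_only requires a visual SNR, got {self.visual_snr!r}")
            if self.auditory_snr != NA or self.soa != NA:
                raise ValueError("visual_only conditions must have n/a auditory SNR and SOA")
            if self.pairing == "mcgurk":
                raise ValueError("mcgurk pairing requires both modalities")
        else:
            if self.auditory_snr not in SNR_LEVELS or self.visual_snr not in SNR_LEVELS:
                raise ValueError("audiovisual conditions require both SNR levels")
            if self.soa not in SOAS:
                raise ValueError(f"audiovisual conditions require an SOA, got {self.soa!r}")
            if self.auditory_snr != "high" and self.visual_snr != "high":
                raise ValueError("the design degrades at most one modality per bimodal cell")

    # -- consonant content -------------------------------------------------

    @property
    def auditory_consonant(self) -> str | None:
        """Consonant of the auditory component ('B' or 'G'), None if absent."""
        if self.modality == "visual_only":
            return None
        return "G" if self.pairing == "congruent_G" else "B"

    @property
    def visual_consonant(self) -> str | None:
        """Consonant of the visual component; the dubbed track is G for mcgurk."""
        if self.modality == "auditory_only":
            return None
        return "B" if self.pairing == "congruent_B" else "G"

    def astuple(self) -> tuple[str, str, str, str, str]:
        return (self.modality, self.pairing, self.auditory_snr, self.visual_snr, self.soa)


@dataclass(frozen=True)
class Design:
    """An ordered collection of unique conditions with a repetition count."""

    conditions: tuple[Condition, ...]
    n_reps: int = 25

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("design contains duplicate conditions")
        if self.n_reps < 0:
            raise ValueError("n_reps must be non-negative")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def index(self, cond: Condition) -> int:
        return self.conditions.index(cond)

    @property
    def audiovisual(self) -> tuple[Condition, ...]:
        return tuple(c for c in self.conditions if c.modality == "audiovisual")

    def to_frame(self) -> pd.DataFrame:
        """One row per condition, columns matching the Condition fields."""
        return pd.DataFrame([c.astuple() for c in self.conditions], columns=_CONDITION_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_design(n_reps: int = 25) -> Design:
    """Build the full 42-condition design in canonical order.

    Ordering is deterministic: auditory-only (B then G, SNR high to low),
    visual-only likewise, then bimodal cells nested pairing -> SNR combination
    -> SOA.  This ordering indexes cross-validation folds, so it must never
    change between runs.
    """
    conditions: list[Condition] = []
    for pairing in ("congruent_B", "congruent_G"):
        for snr in SNR_LEVELS:
            conditions.append(Condition("auditory_only", pairing, auditory_snr=snr))
    for pairing in ("congruent_B", "congruent_G"):
        for snr in SNR_LEVELS:
            conditions.append(Condition("visual_only", pairing, visual_snr=snr))
    for pairing in PAIRINGS:
        for a_snr, v_snr in AV_SNR_COMBOS:
            for soa in SOAS:
                conditions.append(
                    Condition("audiovisual", pairing, auditory_snr=a_snr, visual_snr=v_snr, soa=soa)
                )
    return Design(conditions=tuple(conditions), n_reps=n_reps)


def total_trials(design: Design) -> int:
    """Total number of presentations implied by the design."""
    return len(design.conditions) * design.n_reps
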