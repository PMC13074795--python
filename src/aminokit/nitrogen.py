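"""Nitrogen derivation and nitrogen-corrected profile rescaling.

Nitrogen (g/100 g) is derived from crude protein by dividing by a
food-group-specific nitrogen-to-protein conversion factor.  When a profile
is transferred from a similar food, every present amino acid value is
rescaled by the ratio of target nitrogen to similar-food nitrogen; missing
keys stay missing.  No rounding happens here — report serialization owns
rounding.
"""

from __future__ import annotations

from typing import Mapping

from .datamodel import ValidationError, validate_profile

__all__ = ["nitrogen_from_protein", "nitrogen_corrected_profile"]


def nitrogen_from_protein(protein: float, factor: float) -> float:
    """Nitrogen content (g/100 g) from protein (g/100 g) and a conversion factor."""
    if factor <= 0:
        raise ValidationError(f"conversion factor must be > 0, got {factor}")
    if protein < 0:
        raise ValidationError(f"protein must be >= 0, got {protein}")
    return protein / factor


def nitrogen_corrected_profile(
    similar: Mapping[str, float],
    n_target: float,
    n_similar: float,
) -> dict[str, float]:
    """Rescale a similar food's profile by the nitrogen ratio target/similar.

    The key set is preserved exactly: present keys are scaled, absent keys
    remain absent.
    """
    if n_similar <= 0:
        raise ValidationError(
            f"similar-food nitrogen must be > 0 to scale, got {n_similar}"
        )
    if n_target < 0:
        raise ValidationError(f"target nitrogen must be >= 0, got {n_target}")
    profile = validate_profile(similar)
    if not profile:
        raise ValidationError("similar profile is empty; nothing to scale")
    ratio = n_target / n_similar
    return {key: value * ratio for key, value in profile.items()}
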