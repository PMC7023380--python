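"""Analyte constants: integration windows, proton counts, molar masses.

The five target compounds are quantified from single characteristic
resonance windows in CDCl3 extracts: 16-O-methylcafestol (OMC, the
robusta marker), caffeine, kahweol (the arabica-enriched diterpene),
furfuryl alcohol and 5-hydroxymethylfurfural (HMF, roasting markers).
Windows are stored as (low, high) ppm pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["AnalyteDefinition", "DEFAULT_ANALYTES", "ANALYTE_NAMES",
           "OMC_WINDOW", "OMC_NOISE_WINDOW"]

#: OMC integration window and the equal-width reference window used to
#: cancel the fatty-acid matrix interference that underlies both.
OMC_WINDOW = (3.125, 3.185)
OMC_NOISE_WINDOW = (3.04, 3.10)


@dataclass(frozen=True)
class AnalyteDefinition:
    """Per-analyte constants used throughout simulation and quantification.

    ``recalculation_factor`` corrects a systematic extraction deficit of the
    solution concentration; it is 6 for caffeine (restricted solubility in
    CDCl3, established against an HPLC reference method) and 1 otherwise.
    ``guidance_value_mg_kg`` is the screening threshold, with
    ``guidance_scope`` naming the declaration it applies to.
    """

    name: str
    window_ppm: tuple[float, float]
    center_ppm: float
    n_protons: int
    molar_mass_g_mol: float
    recalculation_factor: float = 1.0
    guidance_value_mg_kg: float | None = None
    guidance_scope: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.window_ppm
        if not lo < hi:
            raise InvalidParameterError(f"{self.name}: window low must be < high")
        if not lo < self.center_ppm < hi:
            raise InvalidParameterError(f"{self.name}: center must lie inside window")
        if self.n_protons < 1:
            raise InvalidParameterError(f"{self.name}: n_protons must be >= 1")
        if self.molar_mass_g_mol <= 0:
            raise InvalidParameterError(f"{self.name}: molar mass must be positive")


def _mid(window: tuple[float, float]) -> float:
    return 0.5 * (window[0] + window[1])


#: Default analyte table. Proton counts are the contributing protons of the
#: integrated signal (O-CH3 for OMC, one N-CH3 for caffeine, single olefinic/
#: furanic/aldehydic protons for the rest); molar masses from standard tables.
DEFAULT_ANALYTES: dict[str, AnalyteDefinition] = {
    a.name: a
    for a in (
        AnalyteDefinition("OMC", OMC_WINDOW, _mid(OMC_WINDOW), 3, 330.46,
                          guidance_value_mg_kg=50.0, guidance_scope="arabica_100"),
        AnalyteDefinition("caffeine", (3.38, 3.44), 3.41, 3, 194.19,
                          recalculation_factor=6.0,
                          guidance_value_mg_kg=1000.0, guidance_scope="decaffeinated"),
        AnalyteDefinition("kahweol", (5.85, 5.925), 5.8875, 1, 314.42,
                          guidance_value_mg_kg=300.0, guidance_scope="robusta_100"),
        AnalyteDefinition("furfuryl_alcohol", (7.39, 7.411), 7.4005, 1, 98.10),
        AnalyteDefinition("HMF", (9.67, 9.69), 9.68, 1, 126.11),
    )
}

ANALYTE_NAMES = tuple(DEFAULT_ANALYTES)
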