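import pandas as pd
import pytest

from perveg.fixtures import REFERENCE_RANGES
from perveg.nutrient_classes import ClassBounds, Nutrient, ReferenceSet


@pytest.fixture(scope="session")
def bounds_set() -> dict[Nutrient, ClassBounds]:
    """Class bounds back-derived from the published reference ranges."""
    return {
        nut: ClassBounds(nutrient=nut, ref_min=lo, ref_max=hi)
        for nut, (lo, hi) in REFERENCE_RANGES.items()
    }


@pytest.fixture(scope="session")
def reference_set() -> ReferenceSet:
    """A minimal two-crop reference set spanning the published ranges."""
    crops = {
        "crop_low": {nut: lo for nut, (lo, hi) in REFERENCE_RANGES.items()},
        "crop_high": {nut: hi for nut, (lo, hi) in REFERENCE_RANGES.items()},
    }
    return ReferenceSet(crops=crops)


@pytest.fixture()
def species_csv(tmp_path):
    path = tmp_path / "species.csv"
    pd.DataFrame(
        [
            {
                "species_name": "Moringa oleifera",
                "family": "Moringaceae",
                "form": "woody",
                "parts": "leaf;unripe_fruit;flowerbud",
                "thermal_climates": "tropical_lowland;subtropical",
                "moisture": "humid;semi_arid",
                "shade": "sun_only",
                "domestication": "minor_global",
                "lifecycle": "perennial",
            },
            {
                "species_name": "Asparagus officinalis",
                "family": "Asparagaceae",
                "form": "herb",
                "parts": "shoot",
                "thermal_climates": "warm_temperate;cold_temperate",
                "moisture": "humid",
                "shade": "sun_only",
                "domestication": "global",
                "lifecycle": "perennial",
            },
            {
                "species_name": "Vitis vinifera",
                "family": "Vitaceae",
                "form": "vine",
                "parts": "leaf",
                "thermal_climates": "warm_temperate;subtropical",
                "moisture": "humid;semi_arid",
                "shade": "partial_shade",
                "domestication": "global",
                "lifecycle": "perennial",
            },
        ]
    ).to_csv(path, index=False)
    return path
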