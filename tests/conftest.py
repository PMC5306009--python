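import pandas as pd
import pytest
from hypothesis import settings

from wolbsurvey import SurveyTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(rows):
    return SurveyTable(pd.DataFrame(rows, columns=[
        "species_id", "order", "family", "habitat", "n_tested", "n_infected",
        "source"]))


@pytest.fixture
def toy_table():
    """Small mixed table: two habitats, a repeat-sampled species, one
    Culicidae record."""
    return make_table([
        ("Aedes_vexans", "Diptera", "Culicidae", "aquatic", 10, 7, "a"),
        ("Baetis_sp1", "Ephemeroptera", "Baetidae", "aquatic", 5, 0, "b"),
        ("Baetis_sp1", "Ephemeroptera", "Baetidae", "aquatic", 10, 2, "b"),
        ("Ischnura_sp", "Odonata", "Coenagrionidae", "aquatic", 3, 1, "c"),
        ("Apis_mellifera", "Hymenoptera", "Apidae", "terrestrial", 20, 15, "d"),
        ("Pieris_rapae", "Lepidoptera", "Pieridae", "terrestrial", 8, 4, "d"),
    ])


@pytest.fixture
def tiny_table():
    """Five aquatic records for oracle comparisons (intercept-only model)."""
    return make_table([
        ("sp1", "Diptera", "", "aquatic", 4, 3, ""),
        ("sp2", "Diptera", "", "aquatic", 7, 0, ""),
        ("sp3", "Odonata", "", "aquatic", 12, 9, ""),
        ("sp4", "Coleoptera", "", "aquatic", 2, 0, ""),
        ("sp5", "Hemiptera", "", "aquatic", 9, 5, ""),
    ])
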