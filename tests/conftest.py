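import pytest

from oximsi.chem import ProbeSpec, build_target_panel, default_panel
from oximsi.profiles import truth_from_observed_ratios
from oximsi.simulate import NoiseModel, ion_amounts, make_design, render


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def probe():
    return ProbeSpec()


@pytest.fixture(scope="session")
def small_screen(panel, probe):
    """A 3-donor x 1-acceptor screen with one planted active donor."""
    donors = ["Leu", "Gly", "Ala"]
    acceptors = ["alpha-KG"]
    targets = build_target_panel([panel[d] for d in donors],
                                 [panel[a] for a in acceptors], probe)
    design = make_design(["E"], donors, acceptors)
    truth = truth_from_observed_ratios("E", {("Leu", "alpha-KG"): 0.5})
    amounts = ion_amounts(design, truth, targets)
    return {"donors": donors, "acceptors": acceptors, "targets": targets,
            "design": design, "truth": truth, "amounts": amounts}


@pytest.fixture()
def small_rendered(small_screen):
    noise = NoiseModel(seed=42)
    dataset, truth_table = render(small_screen["design"], small_screen["amounts"],
                                  noise, small_screen["targets"])
    return {**small_screen, "noise": noise, "dataset": dataset,
            "truth_table": truth_table}


@pytest.fixture()
def noiseless_rendered(small_screen):
    noise = NoiseModel(spot_efficiency_cv=0.0, ion_noise_cv=0.0,
                       baseline_level=0.0, mz_jitter_sd=0.0,
                       center_jitter_px=0.0, seed=0)
    dataset, truth_table = render(small_screen["design"], small_screen["amounts"],
                                  noise, small_screen["targets"])
    return {**small_screen, "noise": noise, "dataset": dataset,
            "truth_table": truth_table}
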