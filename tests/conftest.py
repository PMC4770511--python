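import pytest

from npmine.pipeline import annotate_dataset, report
from npmine.registry import load_registry
from npmine.synth import PROFILES, gen_taxon_panel


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def panels(registry):
    """One synthetic panel per taxon profile (zero mutation, fixed seed)."""
    return {name: gen_taxon_panel(prof, seed=1, registry=registry)
            for name, prof in PROFILES.items()}


@pytest.fixture(scope="session")
def panel_reports(registry, panels):
    """Full pipeline (nt transcripts -> ORFs -> annotation -> report) per taxon."""
    out = {}
    for name, panel in panels.items():
        result = annotate_dataset(panel.transcripts, registry)
        out[name] = (panel, result, report(result, registry))
    return out
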