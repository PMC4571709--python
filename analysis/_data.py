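"""Shared loader for the analysis scripts: reads the synthetic study files
written by 01_simulate_metaweb.py, generating them first if absent."""

from pathlib import Path

import trophoweb as tw

RESULTS = Path(__file__).resolve().parent.parent / "results"
SYN = RESULTS / "synthetic"


def load_study(seed: int = 42):
    if not (SYN / "metaweb.csv").exists():
        import importlib

        simulate = importlib.import_module("01_simulate_metaweb")
        simulate.generate(seed)
    meta = tw.read_web(SYN / "metaweb.csv", SYN / "attributes.csv", name="metaweb")
    region1 = tw.read_species_set(SYN / "region1.txt", "region1")
    region2 = tw.read_species_set(SYN / "region2.txt", "region2")
    newcomers = tw.read_species_set(SYN / "newcomers.txt", "newcomers")
    generalists = tw.read_species_set(SYN / "super_generalists.txt", "super_generalists")
    stations = tw.StationTable.read_csv(SYN / "stations.csv")
    return meta, region1, region2, newcomers, generalists, stations


def three_webs(meta, region1, region2, newcomers):
    w1 = tw.induced_subweb(meta, region1)
    w2 = tw.induced_subweb(meta, region2)
    w2b = tw.add_species(w2, meta, newcomers, name="region2_II")
    return w1, w2, w2b
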