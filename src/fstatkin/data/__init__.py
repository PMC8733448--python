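"""Packaged synthetic frequency panels.

``synthetic_panel.tsv`` is a small synthetic four-population frequency
panel (20 independent loci) generated with
:func:`fstatkin.simulate.synthetic_divergence_panel` (independent
Wright-Fisher drift of Ne = 10^4 diploids for 4000 generations from a
shared Uniform(0.05, 0.95) ancestral frequency, seed 20210715), chosen to
emulate continental-scale human differentiation (pairwise F2 near 0.07,
the scale reported for CEU-YRI).  It is used as the default true-frequency
input of the Monte-Carlo experiments.
"""

from importlib import resources

from ..io import FrequencyPanel, read_frequency_table


def load_synthetic_panel() -> FrequencyPanel:
    """Load the packaged 20-locus, four-population synthetic frequency panel."""
    path = resources.files(__package__) / "synthetic_panel.tsv"
    with resources.as_file(path) as p:
        return read_frequency_table(p)
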