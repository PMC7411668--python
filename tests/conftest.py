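import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pool():
    """Three overlapping source lists with attributes."""
    from weedpool import merge_sources

    flora = [
        {"name": "Cyanus segetum", "family": "Asteraceae",
         "life_form": "therophyte", "origin": "mediterranean",
         "red_list": "listed"},
        {"name": "Papaver rhoeas", "family": "Papaveraceae",
         "life_form": "therophyte", "origin": "european"},
        {"name": "Lolium rigidum", "family": "Poaceae",
         "life_form": "therophyte", "origin": "mediterranean"},
        {"name": "Rumex crispus", "family": "Polygonaceae",
         "life_form": "hemicryptophyte", "origin": "eurasian"},
    ]
    survey = [
        {"name": "Papaver rhoeas"},
        {"name": "Rumex crispus"},
        {"name": "Stellaria media", "life_form": "therophyte",
         "origin": "cosmopolitan"},
    ]
    segetal = [
        {"name": "Cyanus segetum"},
        {"name": "Papaver rhoeas"},
    ]
    return merge_sources({"flora": flora, "survey": survey, "segetal": segetal})


def module_to_truth_map(plot_habitat, truth_plot_habitat):
    """Map detected plot labels to planted habitats by majority vote."""
    from collections import Counter

    votes = {}
    for plot, label in plot_habitat.items():
        if label == "unassigned":
            continue
        votes.setdefault(label, Counter())[truth_plot_habitat[plot]] += 1
    return {label: c.most_common(1)[0][0] for label, c in votes.items()}
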