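import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fast",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def contact_scene():
    """Default contact scene, shared across tests (seed 1)."""
    from ciliaxis import synth

    return synth.make_contact_scene(seed=1)


@pytest.fixture(scope="session")
def contact_pipeline(contact_scene):
    """Segmented masks, skeletons and cilium table for the shared scene."""
    from ciliaxis import contacts as ct
    from ciliaxis import segmentation as sg

    mc, truth = contact_scene
    cil = sg.close_and_filter(sg.otsu_mask(mc["cilia"]), 0.4, 0.05)
    axn = sg.close_and_filter(sg.otsu_mask(mc["axon"]), 0.4, 0.05)
    nuc = sg.close_and_filter(sg.otsu_mask(mc["nuclei"]), 0.4, 0.5)
    cilia_skels = ct.skeletonize_instances(cil)
    axon_skels = ct.skeletonize_instances(axn)
    layer = sg.select_layer(nuc, 1.5)
    centers = sg.nucleus_centers(nuc, erode_radius=0.5)
    table = ct.build_cilium_table(cilia_skels, axon_skels, layer, centers, cilia_mask=cil)
    return {
        "masks": {"cilia": cil, "axon": axn, "nuclei": nuc},
        "cilia_skels": cilia_skels,
        "axon_skels": axon_skels,
        "layer": layer,
        "centers": centers,
        "table": table,
    }


@pytest.fixture(scope="session")
def ratio_scene():
    from ciliaxis import synth

    return synth.make_ratiometric_scene(seed=0)


@pytest.fixture(scope="session")
def flim_scene():
    from ciliaxis import synth

    return synth.make_flim_scene(seed=0)


@pytest.fixture(scope="session")
def trace_set():
    from ciliaxis import synth

    return synth.make_traces(seed=0)


def run_contact_pipeline(seed, params=None):
    """Full segmentation -> skeleton -> distance -> classification pipeline."""
    from ciliaxis import contacts as ct
    from ciliaxis import segmentation as sg
    from ciliaxis import synth

    if params is None:
        mc, truth = synth.make_contact_scene(seed=seed)
    else:
        mc, truth = synth.make_contact_scene(params, seed=seed)
    cil = sg.close_and_filter(sg.otsu_mask(mc["cilia"]), 0.4, 0.05)
    axn = sg.close_and_filter(sg.otsu_mask(mc["axon"]), 0.4, 0.05)
    nuc = sg.close_and_filter(sg.otsu_mask(mc["nuclei"]), 0.4, 0.5)
    cilia_skels = ct.skeletonize_instances(cil)
    axon_skels = ct.skeletonize_instances(axn)
    layer = sg.select_layer(nuc, 1.5)
    centers = sg.nucleus_centers(nuc, erode_radius=0.5)
    table = ct.build_cilium_table(cilia_skels, axon_skels, layer, centers, cilia_mask=cil)
    return mc, truth, cilia_skels, table


def match_instances_to_curves(skels, curves):
    """Map each skeleton instance to the nearest planted centerline index."""
    from scipy.spatial import cKDTree

    spacing = np.asarray(skels.spacing)
    out = []
    for inst in skels.instances:
        um = inst * spacing
        out.append(int(np.argmin([cKDTree(c).query(um)[0].mean() for c in curves])))
    return out
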