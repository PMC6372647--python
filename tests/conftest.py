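import dataclasses

import numpy as np
import pandas as pd
import pytest

import keelquant as kq


@pytest.fixture(scope="session")
def small_wt_config():
    """Short wild-type movie at reduced scale for unit tests."""
    return kq.make_preset("wild_type", seed=7, n_cells=40, duration=30.0, frame_interval=5.0)


@pytest.fixture(scope="session")
def small_wt_truth(small_wt_config):
    return kq.simulate_kinematics(small_wt_config)


@pytest.fixture(scope="session")
def dorsal_render(small_wt_config):
    """A 30-min dorsal movie (onset at 0) with ground-truth labels."""
    cfg = kq.dorsal_run_config(small_wt_config, duration=30.0)
    truth = kq.simulate_kinematics(cfg)
    stack, labels, realised = kq.render_dorsal_view(truth, cfg, return_truth_labels=True)
    return cfg, truth, stack, labels, realised


@pytest.fixture(scope="session")
def transverse_render(small_wt_config):
    truth = kq.simulate_kinematics(small_wt_config)
    return small_wt_config, truth, kq.render_transverse_view(truth, small_wt_config)


def make_truth_frame(cells, frame=0, t_min=0.0):
    """Hand-built ground-truth table for renderer edge cases.

    ``cells`` is a list of dicts with x_um/y_um/z_um and optional shape fields.
    """
    defaults = dict(dorsal_area_um2=50.0, long_axis_um=12.0, angle_deg=0.0,
                    zone="medial", internalised=False, event_time_min=np.nan,
                    constricting=False)
    rows = []
    for i, c in enumerate(cells):
        row = dict(frame=frame, t_min=t_min, cell_id=i, **defaults)
        row.update(c)
        rows.append(row)
    cols = ["frame", "t_min", "cell_id", "x_um", "y_um", "z_um", "dorsal_area_um2",
            "long_axis_um", "angle_deg", "zone", "internalised", "event_time_min",
            "constricting"]
    return pd.DataFrame(rows, columns=cols)
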