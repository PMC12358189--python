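import numpy as np
import pytest

from dcblock import preprocess as pp
from dcblock import synthgen as sg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_labels(events, spike_set, tol_s=1e-3):
    """Match detected events to the nearest planted ground-truth spike.

    Returns an int array per event: the unit id of the closest planted spike
    within ``tol_s``, else -1.
    """
    all_t = np.concatenate(list(spike_set.unit_times.values()))
    all_l = np.concatenate([[uid] * len(t) for uid, t in spike_set.unit_times.items()])
    order = np.argsort(all_t)
    all_t, all_l = all_t[order], all_l[order]
    et = pp.event_times(events)
    idx = np.searchsorted(all_t, et)
    labels = np.empty(len(events), dtype=int)
    for k, (e, i) in enumerate(zip(et, idx)):
        cands = [j for j in (i - 1, i) if 0 <= j < len(all_t)]
        j = min(cands, key=lambda j: abs(all_t[j] - e))
        labels[k] = all_l[j] if abs(all_t[j] - e) < tol_s else -1
    return labels


def sorted_template_session(seed, n_units, modality="noxious_press", n_stimuli=40,
                            snr=8.0):
    """Render one shared-footprint template set and sort it; returns
    (events, refined solution, ground-truth labels)."""
    from dcblock import sorting

    cfg = sg.GeneratorConfig(
        modality=modality, treatment_group="naive", n_units_per_modality=n_units,
        shared_footprint=True, n_pre_sets=1, n_post_sets=0, n_stimuli=n_stimuli,
        snr=snr, seed=seed)
    sess = sg.generate_session(cfg)
    tmpl = sess.sets_by_phase("pre")[0]
    templates = sg.make_templates(n_units, sg.poly2_geometry(3), seed=100 + seed,
                                  snr=snr, noise_sd_uV=cfg.noise_sd_uV)
    v, _ = sg.render_voltage(tmpl, sess.truth, templates, n_channels=3,
                             noise_sd_uV=cfg.noise_sd_uV, seed=seed)
    events = pp.detect_spikes(pp.bandpass(v, rate=30000), rate=30000)
    sol = sorting.fit_template_clustering(events, k_range=range(2, 9), seed=seed)
    sol = sorting.refine_contaminated(sol, events)
    return events, sol, planted_labels(events, tmpl)
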