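import numpy as np
import pytest

import epiamplicon as ea


@pytest.fixture(scope="session")
def pr1_spec():
    """Synthetic 363-nt promoter amplicon, 4 CpGs at +7/+101/+217/+334."""
    return ea.synthetic_promoter_amplicon()


@pytest.fixture(scope="session")
def spikein_spec():
    """Synthetic unmethylated spike-in amplicon (amplicon-local coordinates)."""
    return ea.synthetic_spikein_amplicon()


def site_probs_from_meth(meth, hmc=None):
    """(n,3) state distribution from per-site 5mC (and optional 5hmC) fractions."""
    meth = np.asarray(meth, dtype=float)
    hmc = np.zeros_like(meth) if hmc is None else np.asarray(hmc, dtype=float)
    p = np.stack([1.0 - meth - hmc, meth, hmc], axis=1)
    assert (p >= 0).all()
    return p


def ideal_config(spec, **kw):
    """SimulationConfig with perfect chemistry and no sequencing error."""
    kw.setdefault("conversion_rate", 1.0)
    kw.setdefault("mc_failure_rate", 0.0)
    kw.setdefault("oxbs_hmc_conversion", 1.0)
    kw.setdefault("seq_error_rate", 0.0)
    return ea.SimulationConfig(amplicon=spec, **kw)


def run_pipeline(r1, r2, spec, min_overlap=40):
    """merge → assign → call for a single-amplicon sample."""
    from epiamplicon.amplicon import bisulfite_reference

    merged, counts = ea.merge_pairs(r1, r2, min_overlap=min_overlap)
    bsrefs = {spec.name: bisulfite_reference(spec)}
    profiles = []
    unassigned = 0
    for m in merged:
        name, _ = ea.assign_amplicon(m, [spec], _bsrefs=bsrefs)
        if name is None:
            unassigned += 1
        else:
            profiles.append(ea.call_profile(m, spec))
    return profiles, counts, unassigned
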