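import pytest

import ccmrd


@pytest.fixture(scope="session")
def baseline_params():
    return ccmrd.baseline_parameters()


@pytest.fixture(scope="session")
def solved():
    """Memoized model solves shared across the suite."""
    cache = {}

    def get(model_id, nodes=12, **build_kwargs):
        key = (model_id, nodes, tuple(sorted(build_kwargs.items())))
        if key not in cache:
            model = ccmrd.build_model(model_id, **build_kwargs)
            sol = ccmrd.solve_model(model, nodes_per_compartment=nodes)
            cache[key] = (sol, ccmrd.summarize(sol))
        return cache[key]

    return get
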