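"""Train the pgen-binned thymic selection model on synthetic targets.

The pre-selection pool is the default generative model's productive output;
the "empirical" target is a pgen-biased thinning of it (survival rising
with generation probability, emulating the observed pre/post-selection
shift).  The trained density-ratio factors and merged bin edges are stored
as JSON for the prediction pipeline.
"""

import pathlib

import numpy as np

from naivetcr.selection import selection_mask, train_selection
from naivetcr.synthetic import sample_chain_pool
from naivetcr.vdj import default_model

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
rng = np.random.default_rng(0)

for locus, pool_size in (("alpha", 150_000), ("beta", 300_000)):
    pool = sample_chain_pool(default_model(locus), None, pool_size, rng)
    pre = pool["pgen"].to_numpy()
    # survival bias: smoothly increasing with pgen around a locus-typical value
    pivot = np.median(pre)
    accept = rng.random(len(pre)) < 1 / (1 + (pivot / pre) ** 0.25)
    emp = pre[accept]
    model = train_selection(emp, pre, locus=locus)
    model.to_json(OUT / f"{locus}_selection.json")
    post_mask = selection_mask(
        pre, np.arange(len(pre)), model, rng
    )
    print(
        f"{locus}: {len(model.factors)} merged bins, factors "
        f"{model.factors.min():.2f}-{model.factors.max():.2f}, "
        f"overall survival {post_mask.mean():.3f} "
        f"(overall factor {model.overall_factor:.3f})"
    )
print(f"wrote selection models under {OUT}")
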