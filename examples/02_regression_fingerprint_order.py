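"""Why fingerprint order matters: gradient alone vs gradient + curvature.

For the no-intercept regression toy, resamples with the same gradient at
the original optimum can still have different optima (the curvature
-sum(x^2) varies across resamples), so a first-order fingerprint cannot
pin the optimum down.  Adding the second derivative makes the relation
exact: beta* = beta0 - F1/F2, a Newton step on a quadratic.
"""

import numpy as np

import fpboot as fb

data = fb.simulate_regression(beta=2.0, n=100, seed=7)
model = fb.get_model("regression")
beta0 = model.oracle(data)

rng = np.random.default_rng(1)
fps, opts = [], []
for _ in range(160):
    rb = model.resample(data, rng)
    fps.append(fb.compute_fingerprint(model, rb, beta0, g=2))
    opts.append(model.oracle(rb)[0])

for g in (1, 2):
    pool = fb.TrainingPool()
    for i in range(100):
        v = fps[i].values[:1] if g == 1 else fps[i].values
        pool.add(fb.Fingerprint(v, g, fps[i].eval_cost), np.array([opts[i]]), i)
    fitted = fb.fit(pool)
    train = np.vstack([fps[i].values[: (1 if g == 1 else 2)] for i in range(100)])
    lo, hi = train.min(axis=0), train.max(axis=0)
    errs = []
    for f, o in zip(fps[100:], opts[100:]):
        q = f.values[:1] if g == 1 else f.values
        if np.all(q >= lo) and np.all(q <= hi):
            errs.append(abs(fitted.predict(fb.Fingerprint(q, g, 0))[0][0] - o))
    print(f"g={g}: median prediction error {np.median(errs):.2e} "
          f"(fingerprint costs {fb.compute_fingerprint(model, data, beta0, g=g).eval_cost} "
          f"evaluations per resample)")

print("\nThe g=1 error is a floor set by the information the gradient misses; "
      "the g=2 error is limited only by finite-difference noise.")
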