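# cvte — directed connectivity from complex-valued time series

`cvte` infers the *direction* of coupling between pairs of complex-valued
signals — each supplied as a magnitude series and a phase series, the polar
decomposition z = a·e^{jθ}.  It was built for complex-valued fMRI ROI time
series, where the phase channel carries information that magnitude-only
connectivity analyses discard, but any paired two-channel signals fit the
same interface.

## The measure

The complex-valued transfer entropy from z₁ = (a, θ) to z₂ = (b, φ) sums
four plug-in information quantities at a single coupling lag τ:

    C(z₁→z₂) = R_{a→b} + R_{θ→φ} + R_{a→b|θ} + R_{θ→φ|a}

where R_{x→y} = I(y_t ; x_{t−τ} | y_{t−τ}) is transfer entropy of
four-level symbolized series and R_{x→y|w} conditions additionally on the
third channel's past (partial transfer entropy), capturing
magnitude↔phase cross effects.  Direction is decided from the
surrogate-corrected difference

    ΔC(r) = [C(1→2) − C_sh(1→2; r)] − [C(2→1) − C_sh(2→1; r)],   r = 1..R

over R = 100 time-shuffles of the source signal: a one-sample t-test gates
a three-way verdict (z₁→z₂ / z₂→z₁ / none).  Simplified (`scte`),
magnitude-only (`ste`, `hte`) and Granger baselines, the six-family
simulation benchmark that validates them, and edge-wise two-group
connectivity testing with BH-FDR are included.  See `docs/methods.md` for
the model, its assumptions and its knobs.

## Worked example

Generate a simulated pair with quadratic magnitude coupling and cubic
phase coupling (family N1, planted direction z₁→z₂), and fit the
directed-causality model:

```python
from cvte import PairwiseCausality, generate_pair

pair = generate_pair("N1", T=146, seed=7)
z1, z2 = pair.observed()          # estimator view: |a| and raw phase
res = PairwiseCausality(z1, z2, estimator="cte").fit(R=100, seed=7)
print(res.summary())
```

```
Pairwise directed-causality results
===================================================
estimator                                       cte
signals                                     z1 / z2
T (time points)                                 146
shuffle repetitions R                           100
tau (mag, phase)                             (1, 1)
delta-C mean [bits]                        0.641037
95% CI                         [0.626775, 0.655299]
p-value (ttest)                           2.212e-96
verdict                                     forward
===================================================
Inferred direction: z1 -> z2
```

The coupling lag τ = 1 was recovered by the lagged-correlation scan, the
mean surrogate-corrected causality difference is positive (0.64 bits), and
the verdict matches the planted direction.  `res.delta_c_samples` holds the
R individual differences, `res.causality` the full result record.

Everything is also scriptable from the shell:

```sh
cvte simulate --family L1 --seed 7 -o pair.csv
cvte pairwise pair.csv -o result.csv --estimator cte --R 100 --seed 3
cvte benchmark -o bench/ --methods cte,ste,granger --families L1,N1 --n-pairs 200
```

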