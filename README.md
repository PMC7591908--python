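# lysopos

Quantification of lysosome positioning in single cells, from multichannel
fluorescence images to statistics — with a ground-truth synthetic data
generator so the whole measurement chain is testable end to end.

Anterograde transport shifts lysosomes from the perinuclear cloud around the
microtubule-organizing center toward the plasma membrane, a redistribution
linked to protease secretion, matrix degradation, and invasiveness in cancer
cells.  `lysopos` measures that shift: each cell is mapped onto a normalized
radial coordinate

    r(p) = Dc(p) / (Dc(p) + Db(p)),   r ∈ [0, 1],

where `Dc` is the distance from pixel `p` to the centrosome (γ-tubulin peak)
and `Db` the distance to the cell boundary (α-tubulin mask edge).  The cell
is split into five equal shells of `r` (region 0 innermost … region 4 at the
membrane) and the per-cell readout is the fraction `f_k` of lysosomal
(LAMP1) intensity per region, plus the **peripheral score** `f3 + f4`.
Groups of cells are compared with a normality-driven dispatcher
(D'Agostino–Pearson → Student/Welch t or Mann–Whitney), and cohort-level
analyses (expression-quantile stratification, Kaplan–Meier/logrank,
lymph-node scores via the Brunner–Munzel test) plus closed-form
morphometrics (matrix-degradation ratio, caliper tumor volume) round out the
toolkit.

## Worked example

Simulate two groups of 20 cells whose planted lysosome radii follow
Beta(2, 4) (perinuclear) versus Beta(4, 2) (peripheral), then run the full
pipeline — segmentation, radial profiling, statistical comparison:

```python
from lysopos import pipeline, stats, synthetic

perinuclear = synthetic.SceneParams.small(radial_alpha=2.0, radial_beta=4.0)
peripheral  = synthetic.SceneParams.small(radial_alpha=4.0, radial_beta=2.0)
res = pipeline.run_group_comparison(perinuclear, peripheral,
                                    n_cells_per_group=20, seed=7)

print(res.table.groupby("group")["peripheral_score"].agg(["mean", "sem"]))
t = res.trace
print("method:", t.chosen_method)
print(f"statistic = {t.result.statistic:.2f}, p = {t.result.p_value:.3g}",
      stats.significance_stars(t.result.p_value))
```

```
        mean    sem
group
a      0.269  0.007
b      0.666  0.011
method: welch_t
statistic = -31.16, p = 5.56e-25 ***
```

The peripheral group keeps roughly two thirds of its LAMP1 intensity in the
outer 40% of the centrosome→membrane axis versus about a quarter for the
perinuclear group; both groups pass the normality screen, the F-test flags
unequal variances, and Welch's t-test rejects decisively.

The same operations are available from the shell:

```bash
lysopos simulate scene --seed 1 --out scenes/        # TIFF + JSON truth
lysopos profile --scenes scenes/ --out profiles.csv  # per-cell f0..f4
lysopos compare --table profiles.csv --value peripheral_score --group group
lysopos simulate cohort --seed 1 --out cohort.csv
lysopos survival --cohort cohort.csv --gene-a ARL8B --gene-b BLOC1S2
lysopos measure volume 12 8
```

See `docs/methods.md` for the model, parameter defaults, and the design
decisions behind them.

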