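# agreechart

Agreement charts and chance-corrected concordance statistics for paired
ordinal ratings.

When two raters — two clinicians, a cheap and an expensive diagnostic
method, or the same reader twice — classify the same *n* items into the
same *k* ordered categories, the result is a square contingency table
with cells *n<sub>ij</sub>*. This package computes the standard summary
statistics for such tables and draws the **agreement chart** that shows
the same quantities as areas, for biostatisticians and clinical
researchers assessing inter- or intra-observer reliability.

## Statistics

With row marginals *n<sub>i·</sub>*, column marginals *n<sub>·j</sub>*
and total *n*:

- **Cohen's kappa** — κ = (P<sub>o</sub> − P<sub>e</sub>) / (1 − P<sub>e</sub>),
  where P<sub>o</sub> = Σ<sub>i</sub> n<sub>ii</sub>/n is observed and
  P<sub>e</sub> = Σ<sub>i</sub> n<sub>i·</sub>n<sub>·i</sub>/n² is
  chance-expected agreement. The weighted form credits near misses via
  agreement weights w<sub>ij</sub>; quadratic weights
  w<sub>ij</sub> = 1 − (i−j)²/(k−1)² are the default.
- **Bangdiwala's B-statistic** —
  B = Σ<sub>i</sub> n<sub>ii</sub>² / Σ<sub>i</sub> n<sub>i·</sub>n<sub>·i</sub>:
  in the chart, the area of the dark diagonal squares over the area of
  the marginal rectangles. The weighted form adds the nested
  partial-agreement band areas A<sub>bi</sub>, each credited by the band
  weight w<sub>b</sub>:
  B<sub>w</sub> = Σ<sub>i</sub>(n<sub>ii</sub>² + Σ<sub>b≥1</sub> w<sub>b</sub>A<sub>bi</sub>) / Σ<sub>i</sub> n<sub>i·</sub>n<sub>·i</sub>.

The **agreement chart** places, inside an n × n square, one rectangle
per category (width = column marginal, height = row marginal) stacked
corner to corner, a dark square of side *n<sub>ii</sub>* inside each,
and progressively lighter partial-agreement bands. Perfect agreement
makes every rectangle a square filled by its dark square (B = 1), and
systematic disagreement about category usage (observer bias) shows up as
the "path of rectangles" drifting off the 45° diagonal — a signed,
testable statistic here (`bias_deviation`).

Eight classic example tables ship as CSV fixtures (multiple sclerosis
diagnoses by paired neurologists; cardiovascular cause-of-death
classification; repeat mammographic-density readings on four risk
scales); see `agreechart fixtures list`.

## Worked example

```python
from agreechart import AgreementModel, load_fixture

res = AgreementModel(load_fixture("lrc_elderly")).fit(weights="quadratic")
print(res.summary())
res.render("elderly.svg")   # the agreement chart
```

```
Agreement analysis: Expert panel (rows) vs Nosologist (cols)
categories: CVD, Non-CVD   items: n = 268
----------------------------------------------------------
observed agreement Po       0.8284
chance agreement Pe         0.5996
kappa                       0.5713  [moderate]
weighted kappa (quadratic)  0.5713  [moderate]
B-statistic                 0.7450  [substantial]
weighted B (quadratic)      0.7450  [substantial]
bias path runs below the no-bias diagonal (normalised signed area -0.0896)
```

The expert panel and the nosologist agree on 83% of the 268 elderly
deaths; corrected for chance this is κ = 0.57, and the dark squares
cover B = 0.745 of the marginal-rectangle area. On a 2×2 table the
quadratic weights add nothing (the only off-diagonal band has weight 0),
so the weighted statistics coincide with the unweighted ones. The
negative bias deviation says the path of rectangles runs below the
diagonal: the nosologist (x axis) attributes CVD more liberally than the
expert panel.

The same numbers are available from the shell:

```sh
agreechart stats lrc_elderly --json
agreechart chart lrc_elderly -o elderly.svg
agreechart simulate --marginal 0.3,0.7 --agreement 0.5 --n 100 --seed 9
```

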