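# aromascreen

Odor-activity screening of GC–MS volatile profiles for cooked fragrant
rice (and similar food volatilomics data). Given a compound metadata
table — chemical class, odor threshold in water, GC–O detection flag,
Kovats retention indices — and a compound × cultivar × replicate
content matrix in µg/kg, the package answers the questions a flavor
chemist asks of such data:

* which volatiles are **odor-active** (odor activity value
  OAV_i = C_i / OT_i > 1) and confirmed at the sniffing port,
* which of those are **shared** across all cultivars and how much of
  the total OAV each subset carries,
* how the samples and compounds structure multivariately (PCA, Ward
  HCA, k-means on standardized profiles, two-class OPLS-DA with VIP
  scores and label-permutation validation),
* which compounds **discriminate** a target cultivar in pairwise
  comparisons — the volcano rule VIP > 1.0, FC > 1.2 or FC < 0.8, and
  Benjamini–Hochberg q < 0.05 — and
* how well candidate markers separate the target from the rest
  (ROC/AUC, equal to the Mann–Whitney U over n₁·n₂).

A packaged fixture ships the full annotation and per-cultivar content
table for 45 volatiles from four cooked medium-milled fragrant Simiao
rice cultivars (CV1–CV4), and a synthetic replicate generator
(log-normal noise with exact arithmetic-mean parameterization, a
detection limit, plantable fold-change effects) makes every
replicate-level stage testable without any external data. See
`docs/methods.md` for the full methods note.

## Worked example

Run the whole analysis on the packaged fixture and render the report:

```
$ aromascreen run --out-dir demo
$ aromascreen report --summary demo/summary.json
Volatile odor-activity screening report
========================================
Compounds: 45  (with odor threshold: 29)
By class: alcohol 5, aldehyde 15, ester 6, ether 2, heterocyclic 5, hydrocarbon 2, ketone 8, other 2

Key odor-active compounds (GC-O and OAV > 1): 17
  F1, F10, F12, F19, F2, F25, F28, F3, F39, F4, F42, F43, F5, F6, F7, F8, F9
Shared across all cultivars (OAV > 1 everywhere): 11
  F1, F10, F2, F28, F3, F39, F4, F43, F5, F7, F9

Total OAV per cultivar:
  CV1: 471
  CV2: 375
  CV3: 421
  CV4: 490
Nonanal share of total OAV: 29.9%–47.2% across cultivars
  CV1: 42.5%
  CV2: 29.9%
  CV3: 47.2%
  CV4: 32.2%

Replicate-level screen: skipped (single-replicate input)
```

Reading the numbers: of the 45 identified volatiles, 29 have documented
odor thresholds in water, so only those get defined OAVs. Seventeen
exceed OAV 1 in at least one cultivar *and* were perceived at the GC–O
port — the key odor-active compounds — and 11 of them stay above OAV 1
in every cultivar. Nonanal (F2) alone carries between 29.9% (CV2) and
47.2% (CV3) of each cultivar's total OAV, making it the core of the
shared aroma profile. The fixture stores cultivar-level values as
single replicates, so the t-test/OPLS-DA/ROC stages are skipped
explicitly.

Replicate-level stages run on real triplicates or on synthetic ones:

```
$ aromascreen simulate --seed 4 --cv 0.05 --n-reps 3 \
      --effect F7:CV4:2.0 --out syn.csv
$ aromascreen run --contents syn.csv --out-dir demo_syn
```

which writes per-comparison differential tables
(`diff_CV1_vs_CV4.csv`, ...), Venn memberships, ROC curves per
discriminating key odorant and a machine-readable `summary.json`.

The same operations are available as a library:

```python
import aromascreen as a

table = a.load_compound_table(a.fixture_compound_path())
means = a.cultivar_means(a.load_content_matrix(a.fixture_content_path()))
oav = a.oav_matrix(means, table)
len(a.key_odorants(oav, table))          # 17
len(a.shared_key_odorants(oav, table))   # 11
a.share_range(oav, {table.id_for_name("nonanal")})
# (0.2988591430377606, 0.4722465009896809)
```

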