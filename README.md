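# svnsfuse

Neutrosophic decision fusion for multiclass image classification — built
for eight-class dermoscopy (skin-lesion) tasks such as ISIC 2019, but
generic over any problem with two feature views of the same instances.

## The problem

Two classifiers trained on different feature representations of the same
images disagree, and neither dominates. `svnsfuse` turns that disagreement
into signal. Via error-correcting output codes (ECOC) it trains two opposed
one-vs-all SVM banks: a **true** ensemble on view A (learner *k* fires on
class *k*; decode by highest similarity score) and a **false** ensemble on
view B with the negated coding matrix (learner *k* fires on everything but
class *k*; decode by lowest score). Calibrated scores T_k and F_k for each
class feed a single-valued neutrosophic set (SVNS) characterization:

    I_k  = 1 − |T_k − F_k|            indeterminacy (ambiguity between the ensembles)
    CW_k = [T_k > F_k]                code-word bit
    CR_k = (2 + T_k − I_k − F_k) / 3  crisp value,  0 ≤ T + I + F ≤ 3

Per instance: one set bit → that class; no set bit → argmax I; several set
bits → argmax CR among them. The crisp branch reduces algebraically to
argmax of the score gap T − F, since CR = (1 + 2(T − F))/3 wherever the bit
is set.

The package also ships the surrounding machinery: multi-depth feature-map
fusion (bilinear spatial alignment + channel concatenation + global average
pooling), rich/poor class partitioning with seeded online augmentation for
the minority classes, confusion-matrix metrics, and synthetic two-view data
generators.

## Worked example

The packaged eight-instance fixture pairs a true and a false score matrix
over the classes (AK, BCC, BKL, DF, MEL, NV, SCC, VASC):

```python
import svnsfuse as sf

t, f, truth = sf.worked_example()
for i, p in enumerate(sf.classify(t, f)):
    print(f"instance {p.instance_id}: {p.label:4s} via {p.mode.value:17s} (truth {truth[i]})")
print("argmax-T baseline correct:", (sf.decode_true(t) == truth).sum(), "/ 8")
print("argmin-F baseline correct:", (sf.decode_false(f) == truth).sum(), "/ 8")
```

```
instance 1: NV   via single_bit        (truth NV)
instance 2: MEL  via single_bit        (truth MEL)
instance 3: MEL  via max_crisp         (truth MEL)
instance 4: MEL  via max_crisp         (truth MEL)
instance 5: MEL  via max_indeterminacy (truth MEL)
instance 6: BKL  via max_indeterminacy (truth BKL)
instance 7: BKL  via max_indeterminacy (truth BKL)
instance 8: BCC  via max_crisp         (truth BCC)
argmax-T baseline correct: 3 / 8
argmin-F baseline correct: 6 / 8
```

Either ensemble alone gets 3/8 (true, by argmax) or 6/8 (false, by argmin);
the neutrosophic resolution recovers all 8. Instance 3 shows the crisp
branch at work: both MEL and NV have their bits set, and MEL wins with
CR = 0.486604 against 0.419747 (its indeterminacy there is I = 0.770094 —
a genuinely ambiguous cell).

The same stages are scriptable end to end:

```
svnsfuse simulate --n-classes 8 --instances-per-class 100 --separation 4 --seed 1 --outdir data/
svnsfuse train    --view-a data/view_a.csv --view-b data/view_b.csv --seed 1 --outdir model/
svnsfuse predict  --model model/ --view-a data/view_a.csv --view-b data/view_b.csv --outdir pred/
svnsfuse evaluate --predictions pred/predictions.csv --truth truth.csv --outdir report/
svnsfuse resolve  --true-scores T.csv --false-scores F.csv --outdir out/   # score matrices from elsewhere
```

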