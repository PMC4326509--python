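# ttgedyn

Analysis pipeline for **PCR-TTGE fingerprints of the developing gut
microbiota in very preterm infants**.

Temporal Temperature Gradient Gel Electrophoresis (TTGE) separates
equal-length 16S rDNA amplicons by melting behaviour, so the migration
distance of a gel band is a sequence fingerprint of one dominant taxon in
a stool sample. Longitudinal TTGE surveys — weekly stools from a cohort of
very preterm neonates over their first eight weeks of life — yield
thousands of bands whose interpretation requires a chain of careful steps,
each implemented here as a tested, reusable module:

1. **Standardization** (`ttgedyn.standardize`): each lane carries three
   internal migration standards; a monotone piecewise-linear warp fitted
   through them maps raw distances onto a shared reference coordinate
   system, removing gel-to-gel distortion.
2. **Artifact screening and OTU affiliation** (`ttgedyn.assign`):
   heteroduplex PCR artifacts — chimeric double strands appearing as
   thin/faint bands at the top of the gel or right next to a bright
   band — are flagged and excluded; remaining bands are matched to a
   *diversity ladder* of reference species (nearest entry within a
   tolerance, ties unmatched), and off-ladder bands with an excised-band
   sequence are affiliated to the species-level OTU (SLOTU) of maximal
   global-alignment identity when it exceeds 99%, or mint a new SLOTU.
3. **Taxonomic roll-up** (`ttgedyn.taxonomy`): SLOTUs aggregate to
   genus/family-level groups (GLOTUs; e.g. *Escherichia*, *Enterobacter*
   and *Klebsiella* merge into Enterobacteriaceae, and *Clostridium
   innocuum* belongs to Erysipelotrichaceae despite its name) and further
   to phylum/class-level groups (PLOTUs; Firmicutes split into Bacilli,
   Clostridia and Negativicutes).
4. **Longitudinal statistics** (`ttgedyn.dynamics`): band intensity gives
   a semi-quantitative 0–3 score per OTU and sample; days bin into weeks
   (`ceil(day/7)`); per-infant and cohort-level weekly means, colonized
   fractions, detection periods and OTU diversity are computed, and each
   (infant, OTU) episode is classified **transient** or **persistent** —
   persistent iff more than 50% of the samples after the first recovery
   are positive.
5. **Reporting** (`ttgedyn.report`): band-accounting reconciliation
   (detected = artifact + not-determined + affiliated), per-SLOTU summary
   tables, GLOTU repartition of affiliated bands and per-patient PLOTU
   profiles. A machine-readable transcription of the reference cohort's
   published per-SLOTU summary (30 infants, 354 samples, 50 SLOTUs) ships
   as a packaged fixture.
6. **Simulation** (`ttgedyn.simulate`): a ground-truthed generator of
   synthetic cohorts and gels — onset-week / persistence colonization
   model per GLOTU, affine gel distortion, positional jitter,
   heteroduplex and spurious bands, amplification failures — used for
   end-to-end validation and parameter-recovery testing.

## Worked example

```python
import ttgedyn as t

config = t.SimConfig(seed=1)              # 30-infant synthetic cohort
truth = t.simulate_cohort(config)
rendered = t.render_gels(truth, config)
timeline, assignments = t.analyze_cohort(
    rendered, list(config.standards_reference), config.ladder())

acc = t.reconcile_bands([a for v in assignments.values() for a in v])
print(f"bands: {acc.n_detected} detected = {acc.n_artifact} artifact "
      f"+ {acc.n_unassigned} not determined + {acc.n_affiliated} affiliated")

tmap = t.default_taxonomy()
for glotu in ("Staphylococcus", "Enterococcus", "Enterobacteriaceae"):
    stats = t.cohort_weekly_dynamics(timeline, glotu, tmap)
    frac = {w: round(s.fraction_colonized, 2) for w, s in stats.items()}
    print(f"{glotu:20s} weekly fraction colonized: {frac}")

status = t.colonization_status(timeline, "I001", "Staphylococcus warneri")
print(f"I001 S. warneri: {status.status} "
      f"({status.n_subsequent_positive}/{status.n_subsequent_total} "
      f"positive after first recovery)")
```

prints

```
bands: 898 detected = 229 artifact + 71 not determined + 598 affiliated
Staphylococcus       weekly fraction colonized: {1: 0.82, 2: 0.97, 3: 0.93, 4: 0.86, 5: 0.89, 6: 0.85, 7: 1.0, 8: 0.96}
Enterococcus         weekly fraction colonized: {1: 0.14, 2: 0.17, 3: 0.38, 4: 0.39, 5: 0.46, 6: 0.52, 7: 0.59, 8: 0.58}
Enterobacteriaceae   weekly fraction colonized: {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.04, 5: 0.11, 6: 0.19, 7: 0.22, 8: 0.27}
I001 S. warneri: persistent (11/12 positive after first recovery)
```

About a quarter of the rendered bands are heteroduplex artifacts caught by
the morphology screen, staphylococci colonize nearly every infant from
week 1, and enterobacteria appear only from the second month — the
succession the pipeline is designed to resolve.

The same chain is available from a shell:

```sh
ttgedyn simulate --seed 1 -o simdata/
ttgedyn standardize --bands simdata/bands.tsv \
    --standards simdata/standards_reference.tsv \
    --observed simdata/standards_observed.tsv -o std.tsv
ttgedyn assign --bands std.tsv --ladder simdata/ladder.tsv -o a.tsv
ttgedyn report --bands std.tsv --assignments a.tsv \
    --meta simdata/metadata.tsv -o report/
```

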