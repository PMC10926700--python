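# spikequant

Absolute microbial quantification for metagenomic next-generation
sequencing (mNGS) using synthetic internal-standard (IS) spike-ins.

Plain shotgun mNGS reports read counts, which cannot be compared across
samples: library yield, host DNA content and sequencing depth all change
the read count of a microbe whose absolute load did not change. This
package implements the spike-in calibration strategy used in clinical
mNGS assays: a panel of synthetic dsDNA molecules that do not occur in
nature is added to the library at known masses spanning a concentration
ladder, and their recovered reads calibrate the conversion of every other
read count into mass and then into genome copies. It is aimed at people
building or evaluating quantitative mNGS pipelines: the package designs
panels, simulates spiked sequencing runs with known ground truth,
classifies reads, fits the standard curve and quantifies, and provides
the standard evaluation procedures (depth subsampling, CV% stability,
comparison against reference copy numbers).

## The model

Shotgun sequencing samples nucleic acid approximately uniformly by mass,
so the detected reads *R* of any dsDNA component relate to its input
mass *C* by one sample-wide proportionality:

```
C_is / R_is = C_mic / R_mic
```

The IS panel supplies (C_is, R_is) at five gradient levels (three
molecules per level, 2×10⁻¹ … 2×10⁻⁵ ng/µL, spiked at 2 µL by default).
An ordinary least-squares line is fitted in log10–log10 space,

```
log10 R_is = a · log10 C_is + b        (a ≈ 1 when the mass law holds)
```

and inverted to turn microbial reads R_mic into mass C_mic. Mass becomes
absolute genome copies through the genome length L_mic (bp) and the mass
of one base pair of dsDNA, DNA_c = 650 g·mol⁻¹·bp⁻¹ / N_A ≈ 1.0794×10⁻¹²
ng/bp:

```
COPY_mic = C_mic / (L_mic · DNA_c)
```

Panel molecules are designed under composition constraints (1000-bp
inserts, 970-bp amplifiable core, GC within 35–70 %, homopolymer runs
shorter than four) and accepted only if no 50-mer (either strand) occurs
in the screening references or in any other panel molecule, so IS reads
can never collide with real genomes.

## Worked example

Design a panel, simulate the ten-organism mock community at 20 M reads
with multinomial sampling noise, and quantify:

```python
import spikequant as sq

panel = sq.design_panel(sq.DesignSpec(), seed=7)
comp = sq.preset("mock10", panel)                      # true copies span 10..1e6
counts = sq.simulate_counts(comp, sq.SequencingRun(total_reads=20_000_000, seed=1))
result = sq.quantify_sample(counts, panel, comp.genome_lengths())
print(f"IS curve: slope={result.fit.slope:.4f} r2={result.fit.r_squared:.5f}")
print(result.to_frame())
```

This prints (abbreviated):

```
IS curve: slope=1.0026 intercept=6.5300 r2=0.99999
                taxon_id    reads   copies  true_copies
         mock_ecoli_like      179       10           10
       mock_saureus_like      338     33.8         35.9
 mock_nmeningitidis_like 1.03e+03      131          129
    mock_abaumannii_like 2.45e+04  1.7e+03     1.67e+03
   mock_paeruginosa_like 4.94e+05 2.15e+04     2.15e+04
mock_lmonocytogenes_like 1.09e+07 9.93e+05        1e+06
```

The fitted slope ≈ 1 and r² ≥ 0.99 confirm the mass law across the IS
ladder; estimated copies track the simulated truth over five orders of
magnitude, with the largest relative wobble on the rarest taxon (~180
reads at this depth).

The same workflow is available from the shell:

```
spikequant pipeline --seed 7 --outdir out/
spikequant design --seed 7 --outdir out/      # single stages also work
```

Every artifact (panel FASTA + manifest, count TSV, quantification report,
subsampling CV tables) is written with a JSON provenance sidecar; all
randomness derives from the single `--seed`.

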