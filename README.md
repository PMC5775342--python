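# sarcotex

Automated single-cell analysis of multi-channel cardiomyocyte
immunofluorescence images: marker-based segmentation and subtype
classification, cell morphology, and sarcomere striation quantification by
masked co-occurrence texture analysis.

## Who this is for

Labs evaluating cardiomyocyte maturity — e.g. fibroblasts reprogrammed
toward cardiac fates, or stem-cell-derived cardiomyocytes — from fixed
images stained for DAPI, α-actinin, Hcn4(-GFP) and Nppa.  The package
replaces subjective "does this cell have visible sarcomeres?" calls with
per-cell numbers computed from the pixels of the cell alone.

## What it computes

**Segmentation / classification.** Nuclei from the DAPI channel (closing →
Gaussian → Otsu → small-object removal); marker classes by the strict rule
that a nucleus must lie fully within the Otsu foreground of a marker
channel; Nppa from the 90th-percentile intensity of an 8 px (1.25 μm)
perinuclear ring against a 0.1 threshold; binucleates joined within 25 px
(3.91 μm); cell boundaries by a three-pass sequentially masked
marker-controlled watershed on the Sobel gradient, so adjacent α-actinin⁺
and Hcn4⁺ cells split correctly.

**Morphology.** Area (μm²), elongation (major/minor axis),
circularity 4π·A/P² (1 for a circle), eccentricity of the
same-second-moments ellipse (0 for a circle), major-axis orientation.

**Sarcomere texture.** For a cell mask M and displacement v, a gray-level
co-occurrence matrix p(i,j) is accumulated over all pixel pairs with both
members in M, at 8 intensity bins.  The Haralick correlation

    corr(v) = Σᵢⱼ (i−μᵢ)(j−μⱼ) p(i,j) / (σᵢ σⱼ)

is sampled over 45 angles × 40 offset distances; along the myofibril axis
the trace is a decaying oscillation whose peaks sit at multiples of the
sarcomere spacing.  Reported per cell:

* *sarcomere organization* — maximum peak prominence over all sub-pixel
  interpolated traces (cells at or below 0.1 are treated as unstriated);
* *sarcomere length* — offset of that peak × pixel size (μm);
* *primary sarcomere direction* — angle of the winning trace;
* *cell–sarcomere misalignment* — acute angle to the cell's major axis.

Contrast, uniformity and homogeneity surface variants, plus Gabor
filter-bank and radial-FFT comparator scores, are included for benchmarking;
on the packaged phantom fixture the correlation score separates organized
from disorganized texture better than all five alternatives.

Everything is testable without real micrographs: `sarcotex.synthetic`
generates stripe phantoms with known period/orientation/noise/coverage and
full multi-channel cell fields with exact ground truth.

## Worked example

```python
from sarcotex import make_cell_field, run_pipeline, PipelineConfig, subtype_tally

stack, truth = make_cell_field(n_cells=10, seed=0)   # synthetic 4-channel field
result = run_pipeline(stack, PipelineConfig())        # segment + morphology + texture

cols = ["cell_id", "subtype", "n_nuclei", "area_um2", "elongation",
        "sarcomere_organization", "sarcomere_length_um", "misalignment_deg"]
print(result.table[cols].round(3).to_string(index=False))
```

prints

```
 cell_id           subtype  n_nuclei  area_um2  elongation  sarcomere_organization  sarcomere_length_um  misalignment_deg
       1           actinin         1    58.667       1.930                   1.723                2.012             0.821
       2      actinin+nppa         2    66.357       2.174                   1.704                1.992             1.224
       3              hcn4         1    44.067       1.953                     NaN                  NaN               NaN
       4      actinin+nppa         1    46.338       1.549                   1.673                1.992             0.317
       5           actinin         2    60.645       2.085                   1.696                2.012             1.486
       6 actinin+hcn4+nppa         1    53.149       2.033                   1.682                2.012             2.166
       7              hcn4         1    52.441       1.694                     NaN                  NaN               NaN
       8      actinin+hcn4         1    54.834       1.332                   1.783                2.012             0.591
       9           actinin         1    77.271       1.376                   1.720                2.012             3.559
      10      actinin+hcn4         1    76.074       1.706                   1.764                2.012             0.602
```

Each row is one segmented cell.  The synthetic field renders striation with
a 12.8 px period at 0.15625 μm/px, so the recovered sarcomere lengths of
1.99–2.01 μm for every α-actinin⁺ cell are correct to within the raster;
misalignments are small (0.3–3.6°) because the generator lays striation
along each cell's major axis.  Hcn4-only cells carry no α-actinin texture,
so their striation metrics are absent.  The subtype column reproduces the
generator's marker-combination table exactly (`subtype_tally(result.table)`
gives the Venn-style counts).

## Command line

```bash
sarcotex fixtures out/fixtures            # materialize phantom suite + cell field
sarcotex run --stack field.tif -o out/    # all stages on a multi-page TIFF
sarcotex segment --dapi d.tif --actinin a.tif --hcn4 h.tif --nppa n.tif -o out/
sarcotex compare out/compare              # metric benchmark on the phantom fixture
```

Outputs: `cells.csv` (one row per cell), 16-bit `nucleus_labels.tif` /
`cell_labels.tif`, and `run_metadata.json` echoing every parameter.  All
thresholds live in a YAML config mirroring `PipelineConfig`; re-running with
the same config and inputs is byte-identical.

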