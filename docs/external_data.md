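# Reproducing the outcome-side analyses with external GWAS data

The packaged fixtures cover only the exposure side (the published
instrument tables for benign prostatic hyperplasia and prostatitis). The
full causal estimates additionally need the **prostate-cancer outcome
GWAS** ("Malignant neoplasm of prostate", MRC-IEU, 463 010 European
participants, 2018), which is not shipped: the source publication prints
no dataset accession and the summary statistics are too large to vendor.
Nothing in the test suite or the acceptance report depends on this data.

## Recipe

1. Search the IEU Open GWAS index (https://gwas.mrcieu.ac.uk/) for
   *Malignant neoplasm of prostate*, MRC-IEU consortium, UK Biobank,
   N = 463 010 (the 2018 release). Likewise *Benign prostatic
   hyperplasia* (same cohort) and *Inflammatory diseases of prostate*
   (N = 74 658, 2021) if you want to re-derive the exposure side.
2. Extract the instrument SNPs from the outcome dataset and convert to
   the canonical TSV layout (`SNP EA NEA EAF BETA SE P`), e.g. with
   `bcftools query` on the GWAS-VCF release or the `ieugwaspy` client.
3. Run the pipeline:

   ```yaml
   # config.yaml
   exposure: bph_instruments      # packaged fixture
   outcome: pca_outcome.tsv       # your extracted file
   model: auto_by_q               # random effects when Cochran's Q p < 0.05
   seed: 1
   out_dir: results/bph_vs_pca
   ```

   ```sh
   tsmr run config.yaml
   ```

4. Compare `report.json` against the published numbers: IVW
   (random-effects) OR ≈ 1.209 with log-scale 95% CI 0.098–0.281 and
   p ≈ 5.1e-5, Cochran's Q p ≈ 0.033, Egger intercept ≈ -0.0004
   (p ≈ 0.196), and no outliers from the residual-sum-of-squares
   procedure. Exact agreement depends on matching the dataset release
   and harmonization settings used by the original analysis.
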