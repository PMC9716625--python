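# Independent oracle for the AR(1) random-intercept mixed model.
# Regenerates the frozen reference values in tests/test_stats.py:
#   python -c "import sys; sys.path.insert(0, 'tests'); \
#     from test_stats import _nlme_dataset; \
#     _nlme_dataset().to_csv('lmm_check.csv', index=False)"
#   Rscript tests/oracles/lmm_ar1_oracle.R lmm_check.csv
library(nlme)
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
m <- lme(response ~ x, random = ~1 | participant, data = d,
         correlation = corAR1(form = ~ t | participant/stimulus),
         method = "ML")
cat("beta", fixef(m), "\n")
cat("se", summary(m)$tTable[, 2], "\n")
cat("rho", coef(m$modelStruct$corStruct, unconstrained = FALSE), "\n")
vc <- VarCorr(m)
cat("tau2", as.numeric(vc[1, 1]), "sigma2", as.numeric(vc[2, 1]), "\n")
cat("logLik", logLik(m), "\n")
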