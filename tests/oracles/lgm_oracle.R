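#!/usr/bin/env Rscript
# Independent reference fit of the conditional latent growth model on the
# packaged 69-subject fixture, via nlme (which parameterizes the identical
# likelihood as a linear mixed model):
#   - conditional LGM  = lme(y ~ time*(m, a), random = ~ time | subject,
#                            per-wave residual variances, ML)
#   - FIML-saturated   = gls with per-wave means/slopes and an unstructured
#                        covariance (corSymm x varIdent), ML
#   - CFI baseline     = per-wave independent normals (closed form)
# Writes oracle_lgm69.json next to the fixture.  Run from repo root:
#   Rscript tests/oracles/lgm_oracle.R

suppressMessages({library(nlme); library(jsonlite)})

tab <- read.delim("tests/data/fixture_cohort69.tsv", check.names = FALSE)
n <- nrow(tab)
waves <- c("y1", "y2", "y3")
long <- do.call(rbind, lapply(seq_along(waves), function(w) {
  data.frame(subject = tab$subject, wave = w, time = w - 1,
             y = tab[[waves[w]]], m = tab$mfq_fof, a = tab$age_c)
}))
long <- long[!is.na(long$y), ]
long$wavef <- factor(long$wave)
long <- long[order(long$subject, long$wave), ]

ctrl <- lmeControl(maxIter = 500, msMaxIter = 500, niterEM = 100,
                   tolerance = 1e-9, msTol = 1e-10, opt = "optim",
                   optimMethod = "BFGS")
fit <- lme(y ~ time * m + time * a, random = ~ time | subject,
           weights = varIdent(form = ~ 1 | wavef), data = long,
           method = "ML", control = ctrl)

beta <- fixef(fit)
Psi <- as.matrix(getVarCov(fit))
sigma2 <- fit$sigma^2
ratios <- coef(fit$modelStruct$varStruct, unconstrained = FALSE,
               allCoef = TRUE)
ratios <- ratios[as.character(1:3)]
theta <- sigma2 * ratios^2
ll_model <- as.numeric(logLik(fit))

est <- c("I~1" = unname(beta["(Intercept)"]), "S~1" = unname(beta["time"]),
         "I~mfq_fof" = unname(beta["m"]), "S~mfq_fof" = unname(beta["time:m"]),
         "I~age_c" = unname(beta["a"]), "S~age_c" = unname(beta["time:a"]),
         "I~~I" = Psi[1, 1], "S~~S" = Psi[2, 2], "I~~S" = Psi[1, 2],
         "y1~~y1" = unname(theta[1]), "y2~~y2" = unname(theta[2]),
         "y3~~y3" = unname(theta[3]))

# saturated conditional model: per-wave means/slopes, unstructured Sigma
sat <- gls(y ~ 0 + wavef + wavef:m + wavef:a,
           correlation = corSymm(form = ~ wave | subject),
           weights = varIdent(form = ~ 1 | wavef), data = long,
           method = "ML", control = glsControl(maxIter = 500,
             msMaxIter = 500, tolerance = 1e-9, msTol = 1e-10))
ll_sat <- as.numeric(logLik(sat))
# assemble the unstructured residual covariance
sr <- coef(sat$modelStruct$varStruct, unconstrained = FALSE, allCoef = TRUE)
sr <- sr[as.character(1:3)]
sds <- sat$sigma * sr
cm <- corMatrix(sat$modelStruct$corStruct)[[
  which(sapply(corMatrix(sat$modelStruct$corStruct), nrow) == 3)[1]]]
Sres_sat <- outer(sds, sds) * cm
bsat <- coef(sat)
Csat <- rbind(c(bsat["wavef1:m"], bsat["wavef1:a"]),
              c(bsat["wavef2:m"], bsat["wavef2:a"]),
              c(bsat["wavef3:m"], bsat["wavef3:a"]))
c0sat <- c(bsat["wavef1"], bsat["wavef2"], bsat["wavef3"])

# baseline: per-wave independent normals (free mean and variance)
ll_base <- 0
for (w in 1:3) {
  yv <- long$y[long$wave == w]
  v <- mean((yv - mean(yv))^2)
  ll_base <- ll_base - 0.5 * length(yv) * (log(2 * pi) + log(v) + 1)
}

# joint-moment assembly (sample ML moments of the covariates)
X <- as.matrix(tab[, c("mfq_fof", "age_c")])
mux <- colMeans(X)
Sx <- crossprod(sweep(X, 2, mux)) / n
lam <- cbind(1, 0:2)
Gam <- rbind(c(est["I~mfq_fof"], est["I~age_c"]),
             c(est["S~mfq_fof"], est["S~age_c"]))
C <- lam %*% Gam
PsiM <- rbind(c(est["I~~I"], est["I~~S"]), c(est["I~~S"], est["S~~S"]))
Sres <- lam %*% PsiM %*% t(lam) + diag(theta)
alpha <- c(est["I~1"], est["S~1"])

joint <- function(C, c0, Sres) {
  muy <- c0 + C %*% mux
  Syy <- C %*% Sx %*% t(C) + Sres
  Syx <- C %*% Sx
  list(mu = c(muy, mux),
       Sigma = rbind(cbind(Syy, Syx), cbind(t(Syx), Sx)))
}
jm <- joint(C, lam %*% alpha, Sres)
js <- joint(Csat, c0sat, Sres_sat)

sd_sat <- sqrt(diag(js$Sigma))
Rm <- (js$Sigma - jm$Sigma) / outer(sd_sat, sd_sat)
srmr <- sqrt(mean(Rm[lower.tri(Rm, diag = TRUE)]^2))

df <- 3; df_b <- 9; N <- n
chi2 <- 2 * (ll_sat - ll_model)
chi2_b <- 2 * (ll_sat - ll_base)
dm <- max(chi2 - df, 0); db <- max(chi2_b - df_b, 0)
cfi <- if (max(dm, db) == 0) 1 else 1 - dm / max(dm, db)
rmsea <- sqrt(dm / (df * N))
ncp_for <- function(prob) {
  f <- function(l) pchisq(chi2, df, ncp = l) - prob
  if (f(0) < 0) return(0)
  hi <- max(chi2, 1); while (f(hi) > 0 && hi < 1e8) hi <- hi * 2
  uniroot(f, c(0, hi), tol = 1e-10)$root
}
ci <- c(sqrt(ncp_for(0.975) / (df * N)), sqrt(ncp_for(0.025) / (df * N)))

# standardized solution (model-implied variances; sample SDs for covariates)
Veta <- Gam %*% Sx %*% t(Gam) + PsiM
vary <- diag(lam %*% Veta %*% t(lam)) + theta
sde <- sqrt(diag(Veta)); sdy <- sqrt(vary); sdx <- sqrt(diag(Sx))
std <- c("I~1" = unname(est["I~1"] / sde[1]),
         "S~1" = unname(est["S~1"] / sde[2]),
         "I~mfq_fof" = unname(est["I~mfq_fof"] * sdx[1] / sde[1]),
         "S~mfq_fof" = unname(est["S~mfq_fof"] * sdx[1] / sde[2]),
         "I~age_c" = unname(est["I~age_c"] * sdx[2] / sde[1]),
         "S~age_c" = unname(est["S~age_c"] * sdx[2] / sde[2]),
         "I~~I" = unname(est["I~~I"] / sde[1]^2),
         "S~~S" = unname(est["S~~S"] / sde[2]^2),
         "I~~S" = unname(est["I~~S"] / (sde[1] * sde[2])),
         "y1~~y1" = unname(theta[1] / vary[1]),
         "y2~~y2" = unname(theta[2] / vary[2]),
         "y3~~y3" = unname(theta[3] / vary[3]))

out <- list(loglik_cond = ll_model, loglik_sat_cond = ll_sat,
            loglik_baseline_cond = ll_base,
            estimates = as.list(est), std = as.list(std),
            fit = list(chi2 = chi2, df = df, cfi = cfi, rmsea = rmsea,
                       rmsea_ci_lower = ci[1], rmsea_ci_upper = ci[2],
                       srmr = srmr))
writeLines(toJSON(out, digits = 12, auto_unbox = TRUE),
           "tests/data/oracle_lgm69.json")
cat("wrote tests/data/oracle_lgm69.json\n")
cat(sprintf("ll_model=%.6f ll_sat=%.6f chi2=%.4f cfi=%.4f rmsea=%.4f srmr=%.4f\n",
            ll_model, ll_sat, chi2, cfi, rmsea, srmr))
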