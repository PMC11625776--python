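# Independent R oracle for the Dirichlet regression fit (run once; output
# frozen in dirichlet_oracle_estimates.json). Maximizes the same
# mean/precision Dirichlet likelihood with base-R optim + lgamma only —
# no shared code with the Python implementation.
#
# Data in dirichlet_oracle_data.csv are SYNTHETIC (simulated compositions).
# Usage: Rscript make_dirichlet_oracle.R

d <- read.csv("dirichlet_oracle_data.csv")
Y <- as.matrix(d[, c("y1", "y2", "y3")])
X <- cbind(1, d$x)
p <- ncol(X)

negll <- function(theta) {
  b1 <- theta[1:p]
  b2 <- theta[(p + 1):(2 * p)]
  phi <- exp(theta[2 * p + 1])
  e1 <- exp(X %*% b1)
  e2 <- exp(X %*% b2)
  D <- e1 + e2 + 1
  mu <- cbind(e1 / D, e2 / D, 1 / D)
  a <- phi * mu
  -sum(lgamma(phi) - rowSums(lgamma(a)) + rowSums((a - 1) * log(Y)))
}

fit <- optim(rep(0, 2 * p + 1), negll, method = "BFGS",
             control = list(maxit = 2000, reltol = 1e-14))
stopifnot(fit$convergence == 0)
est <- fit$par
out <- sprintf(
  '{"beta1": [%.10f, %.10f], "beta2": [%.10f, %.10f], "phi": %.10f, "loglik": %.10f}',
  est[1], est[2], est[3], est[4], exp(est[5]), -fit$value
)
writeLines(out, "dirichlet_oracle_estimates.json")
cat(out, "\n")
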