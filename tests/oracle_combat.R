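# Independent ComBat oracle: runs sva::ComBat on every fixture directory
# under the path given as the first argument.  Each fixture dir contains
# Y.csv (samples x features), batch.txt, and optionally cov.txt; the
# harmonized matrix is written back as oracle.csv (samples x features).
suppressMessages(library(sva))
root <- commandArgs(trailingOnly = TRUE)[1]
for (d in list.dirs(root, recursive = FALSE)) {
  Y <- as.matrix(read.csv(file.path(d, "Y.csv"), header = FALSE))
  batch <- readLines(file.path(d, "batch.txt"))
  covf <- file.path(d, "cov.txt")
  mod <- NULL
  if (file.exists(covf)) {
    mod <- model.matrix(~factor(readLines(covf)))
  }
  out <- suppressMessages(ComBat(t(Y), batch, mod = mod))
  write.table(t(out), file.path(d, "oracle.csv"), sep = ",",
              row.names = FALSE, col.names = FALSE)
}
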