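"""Bundled reference tables for worked examples and fixtures.

These are the published top-40 differential-expression summaries
(lncRNA, miRNA, mRNA) and the hub degree list (node degree > 5) from the
HUVEC cyclic-stretch sequencing experiment that motivates this package.
The raw sequencing data behind them is not public, so the printed
summary statistics serve as ground truth for the worked examples: the
FC columns are log2 fold changes (stretch minus control), P is the raw
two-group t-test p-value, FDR the adjusted value, and Regulation the
direction call.

Loaders return DataFrames in the package's DE-table column convention
so they can be fed directly to :func:`cernanet.diffexpr.apply_de_filter`
and :func:`cernanet.network.top_hubs`.
"""

from __future__ import annotations

import io

import pandas as pd

DE_LNCRNA_TSV = """\
gene_id\tgene_symbol\tp_value\tlog2fc\tfdr\tdirection
ENSG00000268575\tAL031282.2\t0.00062\t5.79268\t0.01580\tUp
ENSG00000237813\tAC002066.1\t0.00341\t3.65619\t0.04825\tUp
ENSG00000234378\tAC098828.3\t0.00016\t2.08850\t0.00658\tUp
ENSG00000247095\tMIR210HG\t8.07e-05\t1.79213\t0.00410\tUp
ENSG00000231412\tAC005392.2\t5.17e-05\t1.60687\t0.00297\tUp
ENSG00000275216\tAL161431.1\t3.17e-09\t1.36434\t1.98e-06\tUp
ENSG00000268621\tIGFL2-AS1\t0.00059\t1.13821\t0.01523\tUp
ENSG00000261040\tWFDC21P\t0.00145\t1.96944\t0.02708\tUp
ENSG00000235852\tAC005540.1\t7.91e-10\t1.89379\t9.91e-07\tUp
ENSG00000225855\tRUSC1-AS1\t5.50e-05\t1.88656\t0.00308\tUp
ENSG00000258667\tHIF1A-AS2\t0.00081\t1.84409\t0.01852\tUp
ENSG00000261780\tAC105243.1\t1.99e-08\t1.83428\t8.21e-06\tUp
ENSG00000241316\tSUCLG2-AS1\t1.58e-07\t1.79216\t3.62e-05\tUp
ENSG00000269926\tDDIT4-AS1\t3.87e-08\t1.76033\t1.31e-05\tUp
ENSG00000228437\tLINC02474\t1.87e-05\t1.71344\t0.00141\tUp
ENSG00000231721\tLINC-PINT\t3.13e-07\t1.69794\t6.14e-05\tUp
ENSG00000223901\tAP001469.1\t0.00123\t1.69227\t0.02438\tUp
ENSG00000167046\tAL357033.1\t2.17e-07\t1.67088\t4.62e-05\tUp
ENSG00000214049\tUCA1\t0.00172\t1.66915\t0.03007\tUp
ENSG00000235904\tRBMS3-AS3\t1.30e-07\t1.64632\t3.35e-05\tUp
ENSG00000230552\tAC092162.2\t2.81e-05\t-5.64846\t0.00191\tDown
ENSG00000248802\tAC078850.2\t0.00027\t-4.84467\t0.00909\tDown
ENSG00000234871\tLINC01032\t0.00285\t-3.87282\t0.04276\tDown
ENSG00000272482\tAC254633.1\t8.34e-07\t-3.69988\t0.00012\tDown
ENSG00000259437\tAC093334.1\t0.00308\t-3.48527\t0.04517\tDown
ENSG00000227848\tSUCLA2-AS1\t0.00314\t-3.37469\t0.04590\tDown
ENSG00000258561\tAL359232.1\t0.00047\t-2.50748\t0.01311\tDown
ENSG00000225339\tAL354740.1\t7.71e-07\t-2.31612\t0.00012\tDown
ENSG00000233818\tAP000695.2\t0.00022\t-2.17093\t0.00797\tDown
ENSG00000255864\tAC069208.1\t6.51e-06\t-1.71555\t0.00064\tDown
ENSG00000258969\tLINC02307\t0.00028\t-1.64003\t0.00936\tDown
ENSG00000257114\tLINC02450\t0.00036\t-1.54184\t0.01101\tDown
ENSG00000227925\tLINC01655\t3.40e-07\t-1.46588\t6.51e-05\tDown
ENSG00000275119\tAC244131.2\t0.00281\t-1.38628\t0.04225\tDown
ENSG00000259635\tAC100830.1\t0.00085\t-1.33988\t0.01888\tDown
ENSG00000225791\tTRAM2-AS1\t0.00091\t-1.27027\t0.01999\tDown
ENSG00000238042\tLINC02257\t7.40e-10\t-1.26935\t9.91e-07\tDown
ENSG00000261094\tAC007066.2\t0.00312\t-1.23834\t0.04567\tDown
ENSG00000257176\tAC009318.1\t0.00047\t-1.18344\t0.01311\tDown
ENSG00000226370\tLINC00375\t0.00076\t-1.17222\t0.01790\tDown
"""

DE_MIRNA_TSV = """\
gene_symbol\tp_value\tlog2fc\tavg_expression\tdirection
hsa-miR-151a-5p\t0.00830\t4.967587\t11.843500\tUp
hsa-miR-92a-3p\t0.00552\t4.717289\t13.551630\tUp
hsa-miR-148b-3p\t0.0498\t4.493670\t12.211111\tUp
hsa-miR-21-5p\t0.00539\t4.433062\t16.684564\tUp
hsa-let-7i-5p\t0.00758\t4.169530\t11.920628\tUp
hsa-miR-30a-5p\t0.00624\t4.151897\t12.066384\tUp
hsa-miR-10a-5p\t0.00737\t3.555440\t14.343647\tUp
hsa-miR-99b-5p\t0.01085\t3.496305\t14.620504\tUp
hsa-let-7f-5p\t0.00700\t2.995222\t11.353220\tUp
hsa-miR-222-3p\t0.01295\t2.850281\t10.920330\tUp
hsa-miR-4284\t0.00777\t2.654383\t0.863570\tUp
hsa-miR-374a-5p\t0.01244\t2.405461\t5.723251\tUp
hsa-miR-27b-3p\t0.00747\t2.125160\t11.039688\tUp
hsa-miR-18a-5p\t0.00708\t1.873955\t3.569991\tUp
hsa-miR-96-5p\t0.01107\t1.783202\t7.315302\tUp
hsa-miR-651-5p\t0.0435\t1.776173\t2.523913\tUp
hsa-miR-20a-5p\t0.01147\t1.774804\t7.238996\tUp
hsa-miR-4521\t0.0355\t1.773481\t7.092690\tUp
hsa-miR-210-5p\t0.00520\t1.502487\t2.287306\tUp
hsa-miR-10a-3p\t0.01273\t1.431455\t7.732293\tUp
hsa-miR-100-5p\t0.00749\t-4.78274\t17.89078\tDown
hsa-miR-223-3p\t0.00605\t-4.61353\t0.45163\tDown
hsa-miR-144-3p\t0.03854\t-4.05538\t0.32115\tDown
hsa-miR-142-5p\t0.04626\t-3.43605\t0.83274\tDown
hsa-miR-4772-5p\t0.00895\t-3.15733\t0.86166\tDown
hsa-let-7a-5p\t0.00921\t-2.71715\t13.60388\tDown
hsa-miR-199a-5p\t0.03156\t-2.67627\t1.37259\tDown
hsa-miR-451a\t0.04254\t-2.37644\t2.03836\tDown
hsa-miR-3617-5p\t0.01273\t-2.00633\t0.13456\tDown
hsa-miR-4443\t0.00648\t-1.68771\t0.85807\tDown
hsa-miR-23a-5p\t0.00518\t-1.54230\t1.53357\tDown
hsa-miR-3940-3p\t0.00762\t-1.47825\t1.12245\tDown
hsa-miR-143-3p\t0.00738\t-1.47642\t4.87572\tDown
hsa-miR-191-3p\t0.00607\t-1.44144\t1.31566\tDown
hsa-miR-148a-5p\t0.00701\t-1.33610\t1.32972\tDown
hsa-miR-7976\t0.00962\t-1.29245\t4.13996\tDown
hsa-miR-185-3p\t0.01159\t-1.27379\t1.12633\tDown
hsa-miR-27b-5p\t0.00107\t-1.26108\t3.56518\tDown
hsa-miR-105-5p\t0.01158\t-1.25366\t1.08368\tDown
hsa-miR-576-3p\t0.00686\t-1.16215\t4.20788\tDown
"""

DE_MRNA_TSV = """\
gene_id\tgene_symbol\tp_value\tlog2fc\tfdr\tdirection
ENSG00000125046\tSSUH2\t0.00164\t4.34497\t0.02918\tUp
ENSG00000187134\tAKR1C1\t0.00012\t2.44192\t0.00543\tUp
ENSG00000135373\tEHF\t0.00016\t2.31835\t0.00644\tUp
ENSG00000231924\tPSG1\t0.00105\t2.31706\t0.02229\tUp
ENSG00000145358\tDDIT4L\t0.00070\t2.10851\t0.01696\tUp
ENSG00000182957\tSPATA13\t0.00221\t2.04019\t0.03561\tUp
ENSG00000147872\tPLIN2\t1.22e-07\t1.67389\t3.22e-05\tUp
ENSG00000004799\tPDK4\t1.35e-07\t1.63004\t3.35e-05\tUp
ENSG00000173237\tC11orf86\t0.00016\t1.62141\t0.00633\tUp
ENSG00000100292\tHMOX1\t1.34e-06\t1.60182\t0.00017\tUp
ENSG00000178150\tZNF114\t2.22e-05\t1.55896\t0.00162\tUp
ENSG00000109846\tCRYAB\t3.12e-07\t1.54027\t6.14e-05\tUp
ENSG00000114268\tPFKFB4\t3.11e-07\t1.50759\t6.14e-05\tUp
ENSG00000087086\tFTL\t9.60e-10\t1.46587\t1.04e-06\tUp
ENSG00000120738\tEGR1\t1.11e-07\t1.35264\t3.07e-05\tUp
ENSG00000167996\tFTH1\t8.01e-13\t1.33776\t6.52e-09\tUp
ENSG00000163347\tCLDN1\t6.03e-09\t1.31604\t3.27e-06\tUp
ENSG00000132196\tHSD17B7\t0.00027\t1.24930\t0.00902\tUp
ENSG00000128510\tCPA4\t8.09e-05\t1.23659\t0.00410\tUp
ENSG00000104419\tNDRG1\t1.08e-09\t1.20327\t1.10e-06\tUp
ENSG00000244588\tRAD21L1\t5.43e-05\t-6.29595\t0.00305\tDown
ENSG00000268434\tAC011530.1\t0.00276\t-4.12341\t0.04191\tDown
ENSG00000198049\tAVPR1B\t0.00341\t-3.74115\t0.04818\tDown
ENSG00000269955\tC7orf55\t0.00108\t-3.40469\t0.02263\tDown
ENSG00000140807\tNKD1\t0.00221\t-3.15605\t0.03561\tDown
ENSG00000112139\tMDGA1\t0.00029\t-2.51469\t0.00953\tDown
ENSG00000118557\tPMFBP1\t0.00058\t-2.43974\t0.01516\tDown
ENSG00000162496\tDHRS3\t4.02e-14\t-2.41244\t0.00000\tDown
ENSG00000141469\tSLC14A1\t0.00097\t-2.10327\t0.02102\tDown
ENSG00000102174\tPHEX\t0.00054\t-2.06964\t0.01443\tDown
ENSG00000214279\tSCART1\t0.00039\t-1.83248\t0.01167\tDown
ENSG00000065320\tNTN1\t0.00145\t-1.81924\t0.02707\tDown
ENSG00000260851\tAC010542.3\t0.00214\t-1.80247\t0.03497\tDown
ENSG00000273167\tAL359736.1\t0.00024\t-1.78956\t0.00822\tDown
ENSG00000175093\tSPSB4\t0.00012\t-1.78920\t0.00528\tDown
ENSG00000054219\tLY75\t0.00072\t-1.68978\t0.01736\tDown
ENSG00000171189\tGRIK1\t0.00063\t-1.66405\t0.01580\tDown
ENSG00000104728\tARHGEF10\t0.00280\t-1.64612\t0.04222\tDown
ENSG00000134955\tSLC37A2\t1.42e-06\t-1.64513\t0.00018\tDown
ENSG00000135205\tCCDC146\t0.00046\t-1.63602\t0.01302\tDown
"""

DEGREES_TSV = """\
rank\tbiotype\tnode_id\tdegree
1\tmiRNA\thsa-miR-4739\t35
2\tlncRNA\tNEAT1\t18
3\tmiRNA\thsa-miR-6756-5p\t17
4\tmiRNA\thsa-miR-4685-5p\t16
5\tmiRNA\thsa-miR-5787\t14
6\tmiRNA\thsa-miR-15a-5p\t12
7\tmiRNA\thsa-miR-619-5p\t12
8\tmRNA\tMAP3K2\t11
9\tmiRNA\thsa-miR-424-5p\t11
10\tmiRNA\thsa-miR-15b-5p\t11
11\tmiRNA\thsa-miR-497-5p\t11
12\tmiRNA\thsa-miR-16-5p\t11
13\tmiRNA\thsa-miR-6779-5p\t11
14\tmiRNA\thsa-miR-6848-5p\t10
15\tmRNA\tRASA1\t10
16\tmiRNA\thsa-miR-195-5p\t10
17\tmiRNA\thsa-miR-5001-5p\t10
18\tmRNA\tMAP4K4\t9
19\tmRNA\tPTPRJ\t9
20\tmiRNA\thsa-miR-4728-5p\t8
"""


def _read(tsv: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(tsv), sep="\t")


def load_reference_de_lncrna() -> pd.DataFrame:
    """Top-40 differentially expressed lncRNAs (20 up, 20 down)."""
    df = _read(DE_LNCRNA_TSV)
    df["biotype"] = "lncRNA"
    return df


def load_reference_de_mirna() -> pd.DataFrame:
    """Top-40 differentially expressed miRNAs; no FDR column was published."""
    df = _read(DE_MIRNA_TSV)
    df["biotype"] = "miRNA"
    return df


def load_reference_de_mrna() -> pd.DataFrame:
    """Top-40 differentially expressed mRNAs (20 up, 20 down)."""
    df = _read(DE_MRNA_TSV)
    df["biotype"] = "mRNA"
    return df


def load_reference_degrees() -> pd.DataFrame:
    """Published hub list: the 20 network nodes with degree > 5."""
    return _read(DEGREES_TSV)
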