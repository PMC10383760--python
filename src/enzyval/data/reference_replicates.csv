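wine_id,procedure,replicate_index,value_g_per_L
dry_red,automated,1,2.64
dry_red,automated,2,2.655
dry_red,automated,3,2.621
dry_red,automated,4,2.624
dry_red,automated,5,2.643
dry_red,automated,6,2.652
dry_red,automated,7,2.622
dry_red,automated,8,2.579
dry_red,automated,9,2.603
dry_red,automated,10,2.587
dry_red,manual,1,2.447
dry_red,manual,2,2.48
dry_red,manual,3,2.44
dry_red,manual,4,2.435
dry_red,manual,5,2.402
dry_red,manual,6,2.355
dry_red,manual,7,2.434
dry_red,manual,8,2.373
dry_red,manual,9,2.398
dry_red,manual,10,2.405
dry_white,automated,1,1.678
dry_white,automated,2,1.658
dry_white,automated,3,1.651
dry_white,automated,4,1.652
dry_white,automated,5,1.65
dry_white,automated,6,1.637
dry_white,automated,7,1.64
dry_white,automated,8,1.636
dry_white,automated,9,1.663
dry_white,automated,10,1.64
dry_white,manual,1,1.679
dry_white,manual,2,1.66
dry_white,manual,3,1.661
dry_white,manual,4,1.639
dry_white,manual,5,1.725
dry_white,manual,6,1.623
dry_white,manual,7,1.726
dry_white,manual,8,1.745
dry_white,manual,9,1.756
dry_white,manual,10,1.738
moderately_sweet,automated,1,7.08
moderately_sweet,automated,2,7.051
moderately_sweet,automated,3,6.986
moderately_sweet,automated,4,6.95
moderately_sweet,automated,5,6.919
moderately_sweet,automated,6,6.955
moderately_sweet,automated,7,6.959
moderately_sweet,automated,8,7.053
moderately_sweet,automated,9,6.995
moderately_sweet,automated,10,7.012
moderately_sweet,manual,1,7.187
moderately_sweet,manual,2,7.256
moderately_sweet,manual,3,7.235
moderately_sweet,manual,4,7.137
moderately_sweet,manual,5,7.29
moderately_sweet,manual,6,7.101
moderately_sweet,manual,7,7.317
moderately_sweet,manual,8,7.243
moderately_sweet,manual,9,7.378
moderately_sweet,manual,10,7.346
sweet,automated,1,31.767
sweet,automated,2,31.09
sweet,automated,3,30.262
sweet,automated,4,31.793
sweet,automated,5,31.325
sweet,automated,6,31.583
sweet,automated,7,31.124
sweet,automated,8,31.197
sweet,automated,9,31.582
sweet,automated,10,31.912
sweet,manual,1,32.541
sweet,manual,2,33.125
sweet,manual,3,32.823
sweet,manual,4,32.979
sweet,manual,5,32.751
sweet,manual,6,31.077
sweet,manual,7,34.02
sweet,manual,8,31.683
sweet,manual,9,31.463
sweet,manual,10,32.483
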