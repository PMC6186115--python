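category,weight,code_prefix
mi,1,410
mi,1,412
chf,1,428
pvd,1,441
pvd,1,443.9
pvd,1,785.4
pvd,1,V43.4
cvd,1,430
cvd,1,431
cvd,1,432
cvd,1,433
cvd,1,434
cvd,1,435
cvd,1,436
cvd,1,437
cvd,1,438
dementia,1,290
cpd,1,490
cpd,1,491
cpd,1,492
cpd,1,493
cpd,1,494
cpd,1,495
cpd,1,496
cpd,1,500
cpd,1,501
cpd,1,502
cpd,1,503
cpd,1,504
cpd,1,505
cpd,1,506.4
rheum,1,710.0
rheum,1,710.1
rheum,1,710.4
rheum,1,714.0
rheum,1,714.1
rheum,1,714.2
rheum,1,714.81
rheum,1,725
pud,1,531
pud,1,532
pud,1,533
pud,1,534
mild_liver,1,571.2
mild_liver,1,571.4
mild_liver,1,571.5
mild_liver,1,571.6
diabetes,1,250.0
diabetes,1,250.1
diabetes,1,250.2
diabetes,1,250.3
diabetes,1,250.7
diabetes_compl,2,250.4
diabetes_compl,2,250.5
diabetes_compl,2,250.6
plegia,2,342
plegia,2,344.1
renal,2,582
renal,2,583.0
renal,2,583.1
renal,2,583.2
renal,2,583.3
renal,2,583.4
renal,2,583.5
renal,2,583.6
renal,2,583.7
renal,2,585
renal,2,586
renal,2,588
malignancy,2,140
malignancy,2,141
malignancy,2,142
malignancy,2,143
malignancy,2,144
malignancy,2,145
malignancy,2,146
malignancy,2,147
malignancy,2,148
malignancy,2,149
malignancy,2,150
malignancy,2,151
malignancy,2,152
malignancy,2,153
malignancy,2,154
malignancy,2,155
malignancy,2,156
malignancy,2,157
malignancy,2,158
malignancy,2,159
malignancy,2,160
malignancy,2,161
malignancy,2,162
malignancy,2,163
malignancy,2,164
malignancy,2,165
malignancy,2,166
malignancy,2,167
malignancy,2,168
malignancy,2,169
malignancy,2,170
malignancy,2,171
malignancy,2,172
malignancy,2,174
malignancy,2,175
malignancy,2,176
malignancy,2,177
malignancy,2,178
malignancy,2,179
malignancy,2,180
malignancy,2,181
malignancy,2,182
malignancy,2,183
malignancy,2,184
malignancy,2,185
malignancy,2,186
malignancy,2,187
malignancy,2,188
malignancy,2,189
malignancy,2,190
malignancy,2,191
malignancy,2,192
malignancy,2,193
malignancy,2,194
malignancy,2,195
malignancy,2,200
malignancy,2,201
malignancy,2,202
malignancy,2,203
malignancy,2,204
malignancy,2,205
malignancy,2,206
malignancy,2,207
malignancy,2,208
severe_liver,3,456.0
severe_liver,3,456.1
severe_liver,3,456.2
severe_liver,3,572.2
severe_liver,3,572.3
severe_liver,3,572.4
severe_liver,3,572.8
mets,6,196
mets,6,197
mets,6,198
mets,6,199.0
mets,6,199.1
aids,6,042
aids,6,043
aids,6,044
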